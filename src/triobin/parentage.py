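"""Mendelian-exclusion parentage verification for an interspecies trio.

Counts sites where a putative trio's genotypes are impossible under
biparental inheritance.  Sites bearing the interspecies-cross signature —
sire homozygous for the reference allele, dam homozygous for the alternate,
child heterozygous — are ignored: that pattern is produced by *any*
cattle x yak mating and carries no parentage information.  A true parent
should show many-fold fewer exclusions than an unrelated animal of the same
lineage; genotyping error (undersampled heterozygotes at low coverage) sets
the floor for the true trio's rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from . import io

Genotype = tuple[int, int]  # unordered allele pair, 0 = ref, 1 = alt


@dataclass
class TrioSite:
    chrom: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    sire_gt: Genotype | None
    dam_gt: Genotype | None
    child_gt: Genotype | None


@dataclass
class ExclusionReport:
    sire_id: str
    dam_id: str
    child_id: str
    n_sites_analyzed: int
    n_signature_ignored: int
    n_exclusions: int
    n_skipped: int  # multiallelic / missing-genotype / non-polymorphic sites

    @property
    def exclusion_rate(self) -> float:
        if self.n_sites_analyzed == 0:
            return float("nan")
        return self.n_exclusions / self.n_sites_analyzed


def mendelian_consistent(
    sire_gt: Genotype, dam_gt: Genotype, child_gt: Genotype
) -> bool:
    """True iff the child's allele pair can be formed by drawing one allele
    from the sire and one from the dam.  Missing genotypes are rejected."""
    for gt in (sire_gt, dam_gt, child_gt):
        if gt is None or None in gt:
            raise ValueError("mendelian_consistent requires complete genotypes")
    c1, c2 = child_gt
    for s in sire_gt:
        for d in dam_gt:
            if (c1, c2) == (s, d) or (c1, c2) == (d, s):
                return True
    return False


def interspecies_signature(site: TrioSite, strict: bool = True) -> bool:
    """The fixed cross signature: sire hom-ref, dam hom-alt, child het.

    With ``strict=False`` any hom x opposite-hom -> het pattern qualifies
    (sensitivity variant; the strict form requires the sire homozygous for
    the reference allele specifically).
    """
    s, d, c = site.sire_gt, site.dam_gt, site.child_gt
    if s is None or d is None or c is None:
        return False
    het_child = set(c) == {0, 1}
    if strict:
        return s == (0, 0) and d == (1, 1) and het_child
    return (
        het_child
        and s[0] == s[1]
        and d[0] == d[1]
        and s[0] != d[0]
    )


def _gt_of(sample) -> Genotype | None:
    alleles = sample.get("GT")
    if alleles is None or any(a is None for a in alleles) or len(alleles) != 2:
        return None
    return (min(alleles), max(alleles))


def iter_trio_sites(
    vcf_path, sire_id: str, dam_id: str, child_id: str
) -> Iterable[tuple[TrioSite, bool]]:
    """Yield (site, is_multiallelic) for every record of a VCF."""
    vcf = io.open_vcf(vcf_path)
    for sid in (sire_id, dam_id, child_id):
        if sid not in vcf.header.samples:
            raise KeyError(f"sample {sid!r} not present in VCF")
    for rec in vcf:
        multi = rec.alts is not None and len(rec.alts) > 1
        alt = rec.alts[0] if rec.alts else ""
        site = TrioSite(
            chrom=rec.chrom,
            pos=rec.pos,
            ref_allele=rec.ref,
            alt_allele=alt,
            sire_gt=_gt_of(rec.samples[sire_id]),
            dam_gt=_gt_of(rec.samples[dam_id]),
            child_gt=_gt_of(rec.samples[child_id]),
        )
        yield site, multi


def count_exclusions(
    vcf_path,
    sire_id: str,
    dam_id: str,
    child_id: str,
    strict_signature: bool = True,
) -> ExclusionReport:
    """Exclusion count over biallelic sites polymorphic in the tested trio.

    A site enters the denominator when all three genotypes are present, the
    site is biallelic, at least two distinct alleles appear among the three
    genotypes, and the interspecies signature does not apply (signature
    sites are tallied separately).
    """
    n_analyzed = n_signature = n_excl = n_skipped = 0
    for site, multi in iter_trio_sites(vcf_path, sire_id, dam_id, child_id):
        if multi:
            n_skipped += 1
            continue
        gts = (site.sire_gt, site.dam_gt, site.child_gt)
        if any(g is None for g in gts):
            n_skipped += 1
            continue
        observed = {a for g in gts for a in g}
        if len(observed) < 2:  # not polymorphic in the trio
            n_skipped += 1
            continue
        if interspecies_signature(site, strict=strict_signature):
            n_signature += 1
            continue
        n_analyzed += 1
        if not mendelian_consistent(site.sire_gt, site.dam_gt, site.child_gt):
            n_excl += 1
    return ExclusionReport(
        sire_id=sire_id,
        dam_id=dam_id,
        child_id=child_id,
        n_sites_analyzed=n_analyzed,
        n_signature_ignored=n_signature,
        n_exclusions=n_excl,
        n_skipped=n_skipped,
    )


def parentage_report(
    vcf_path,
    child_id: str,
    candidate_sires: list[str],
    candidate_dams: list[str],
    true_sire: str | None = None,
    true_dam: str | None = None,
) -> dict:
    """Test every candidate parent while holding the other role fixed.

    Each candidate sire is paired with the fixed dam (``true_dam``, default
    the first candidate dam) and vice versa.  The verdict names, per role,
    the candidate with the minimal exclusion rate, together with the
    fold-difference to the best (lowest-rate) rejected candidate of that
    role; a fold-difference is None when only one candidate was offered.
    """
    if not candidate_sires or not candidate_dams:
        raise ValueError("at least one candidate per role is required")
    fixed_sire = true_sire or candidate_sires[0]
    fixed_dam = true_dam or candidate_dams[0]
    reports: list[ExclusionReport] = []
    for sire in sorted(set(candidate_sires)):
        reports.append(count_exclusions(vcf_path, sire, fixed_dam, child_id))
    for dam in sorted(set(candidate_dams)):
        if (fixed_sire, dam) not in {(r.sire_id, r.dam_id) for r in reports}:
            reports.append(count_exclusions(vcf_path, fixed_sire, dam, child_id))

    def _verdict(role: str, candidates: list[str]) -> dict:
        cand = sorted(set(candidates))
        rates = {}
        for c in cand:
            matches = [
                r
                for r in reports
                if (r.sire_id if role == "sire" else r.dam_id) == c
            ]
            rates[c] = min(m.exclusion_rate for m in matches)
        best = min(rates, key=lambda c: (rates[c], c))
        others = [rates[c] for c in cand if c != best]
        fold = (min(others) / rates[best]) if others and rates[best] > 0 else (
            float("inf") if others else None
        )
        return {"assigned": best, "rate": rates[best], "fold_vs_best_control": fold}

    return {
        "reports": reports,
        "sire": _verdict("sire", candidate_sires),
        "dam": _verdict("dam", candidate_dams),
    }
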