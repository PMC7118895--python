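"""Window SNP-rate phasing confirmation and introgression flagging.

Short reads from panels of known cattle and known yak are aligned to each
haplotype assembly upstream; per-sample pileups are genotyped here and
summarized as window SNP rates,

    rate = (n_hom + 0.5 * n_het) / n_genotyped_bases

over fixed 50-kb tiles.  A correctly phased yak (maternal) assembly should
show higher cattle-panel than yak-panel rates in almost every window, and
vice versa for the cattle (paternal) assembly.  Windows where the pattern
inverts on one assembly but not the other are candidate introgression
segments; reciprocal inversions on both assemblies are candidate haplotype
switch errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import io

WINDOW = 50_000

REF = "REF"
HET = "HET"
HOM_ALT = "HOM_ALT"
NOCALL = "NOCALL"


@dataclass
class SiteCall:
    chrom: str
    pos: int  # 1-based, as in the pileup
    depth: int
    call: str


@dataclass
class WindowRate:
    chrom: str
    start: int  # 0-based half-open window start
    n_hom: int
    n_het: int
    n_genotyped_bases: int

    @property
    def rate(self) -> float:
        """(hom + 0.5*het) / genotyped bases; NaN when nothing genotyped."""
        if self.n_genotyped_bases == 0:
            return float("nan")
        return (self.n_hom + 0.5 * self.n_het) / self.n_genotyped_bases

    @property
    def defined(self) -> bool:
        return self.n_genotyped_bases > 0


@dataclass
class PanelComparison:
    """Per-window panel means and the every-individual extremes.

    ``fraction_a_higher`` is computed over decided windows: both means
    defined and not tied.  ``min_a``/``max_b`` etc. support the strict
    all-individuals discordance rule.
    """

    chrom_starts: list[tuple[str, int]]
    mean_a: np.ndarray
    mean_b: np.ndarray
    min_a: np.ndarray
    max_a: np.ndarray
    min_b: np.ndarray
    max_b: np.ndarray
    a_higher: np.ndarray = field(init=False)
    decided: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        defined = ~(np.isnan(self.mean_a) | np.isnan(self.mean_b))
        self.decided = defined & (self.mean_a != self.mean_b)
        self.a_higher = self.decided & (self.mean_a > self.mean_b)

    @property
    def fraction_a_higher(self) -> float:
        n = int(self.decided.sum())
        if n == 0:
            return float("nan")
        return float(self.a_higher.sum()) / n

    def discordant_windows(self) -> np.ndarray:
        """Windows where every panel-A individual exceeds every panel-B one.

        With panel A = the assembly's own species, these are the windows
        whose pattern inverts the phasing expectation.
        """
        ok = ~(np.isnan(self.min_a) | np.isnan(self.max_b))
        return ok & (self.min_a > self.max_b)


def compute_depth_bounds(
    depths_or_pileup: Iterable, lo_pct: float = 2.5, hi_pct: float = 97.5
) -> tuple[int, int]:
    """Per-sample retention bounds: symmetric nearest-rank percentiles.

    The low bound is the ceil(lo_pct% * N)-th smallest depth and the high
    bound the ceil((100-hi_pct)% * N)-th largest; retention is inclusive of
    both bounds.  Accepts an iterable of depths or of PileupRecords.
    """
    depths = np.fromiter(
        (
            d.depth if isinstance(d, io.PileupRecord) else int(d)
            for d in depths_or_pileup
        ),
        dtype=np.int64,
    )
    if depths.size == 0:
        raise ValueError("cannot compute depth bounds on an empty stream")
    s = np.sort(depths)
    n = s.size
    lo_rank = max(1, math.ceil(n * lo_pct / 100.0))
    hi_rank = max(1, math.ceil(n * (100.0 - hi_pct) / 100.0))
    return int(s[lo_rank - 1]), int(s[n - hi_rank])


def call_site(
    record: io.PileupRecord,
    depth_bounds: tuple[int, int],
    het_min: float = 0.2,
    hom_min: float = 0.8,
) -> SiteCall:
    """Genotype one pileup position from its base column.

    NOCALL outside the inclusive depth bounds or with zero usable bases;
    otherwise the non-reference allele fraction f over usable base calls
    decides: f >= hom_min -> HOM_ALT, het_min <= f < hom_min -> HET,
    f < het_min -> REF.  A malformed base column is NOCALL with a warning.
    """
    lo, hi = depth_bounds
    if record.depth < lo or record.depth > hi:
        return SiteCall(record.chrom, record.pos, record.depth, NOCALL)
    try:
        n_ref, n_alt = io.pileup_base_counts(record)
    except ValueError as e:
        io.log("phase-qc", f"{record.chrom}:{record.pos}: {e}")
        return SiteCall(record.chrom, record.pos, record.depth, NOCALL)
    usable = n_ref + n_alt
    if usable == 0:
        return SiteCall(record.chrom, record.pos, record.depth, NOCALL)
    f = n_alt / usable
    if f >= hom_min:
        call = HOM_ALT
    elif f >= het_min:
        call = HET
    else:
        call = REF
    return SiteCall(record.chrom, record.pos, record.depth, call)


def window_snp_rates(
    calls: Iterable[SiteCall], window: int = WINDOW
) -> list[WindowRate]:
    """Aggregate sorted site calls into fixed tiles anchored at position 0.

    Genotyped bases count REF, HET and HOM_ALT calls; NOCALL positions do
    not enter the denominator.  Input must be position-sorted per
    chromosome (chunk-splitting a stream does not change the result).
    """
    acc: dict[tuple[str, int], list[int]] = {}
    last: dict[str, int] = {}
    for c in calls:
        if last.get(c.chrom, 0) > c.pos:
            raise ValueError(
                f"unsorted input: {c.chrom}:{c.pos} after {last[c.chrom]}"
            )
        last[c.chrom] = c.pos
        start = ((c.pos - 1) // window) * window
        a = acc.setdefault((c.chrom, start), [0, 0, 0])
        if c.call == NOCALL:
            continue
        if c.call == HOM_ALT:
            a[0] += 1
        elif c.call == HET:
            a[1] += 1
        a[2] += 1
    out = [
        WindowRate(chrom, start, hom, het, n)
        for (chrom, start), (hom, het, n) in sorted(acc.items())
    ]
    for w in out:
        if not w.defined:
            io.log("phase-qc", f"window {w.chrom}:{w.start} has no genotyped bases")
    return out


def pileup_to_window_rates(
    records: Sequence[io.PileupRecord], window: int = WINDOW, **call_kwargs
) -> list[WindowRate]:
    """Convenience: depth bounds, site calls and window rates for one sample."""
    bounds = compute_depth_bounds(records)
    calls = (call_site(r, bounds, **call_kwargs) for r in records)
    return window_snp_rates(calls, window=window)


def _rate_table(
    rates_by_individual: dict[str, list[WindowRate]]
) -> tuple[list[tuple[str, int]], dict[str, np.ndarray]]:
    grid: set[tuple[str, int]] = set()
    for rates in rates_by_individual.values():
        grid.update((w.chrom, w.start) for w in rates)
    ordered = sorted(grid)
    index = {key: i for i, key in enumerate(ordered)}
    table = {}
    for ind, rates in rates_by_individual.items():
        col = np.full(len(ordered), np.nan)
        for w in rates:
            if w.defined:
                col[index[(w.chrom, w.start)]] = w.rate
        table[ind] = col
    return ordered, table


def compare_panels(
    rates_by_individual: dict[str, list[WindowRate]],
    panel_a: set[str],
    panel_b: set[str],
) -> PanelComparison:
    """Per-window panel means and the share of windows where panel A is higher.

    Individuals with an undefined rate in a window are dropped from that
    window's mean; windows where either panel mean is undefined, or the two
    means tie, are undecided and excluded from the fraction's denominator.
    """
    if not panel_a or not panel_b:
        raise ValueError("both panels must be non-empty")
    missing = (set(panel_a) | set(panel_b)) - set(rates_by_individual)
    if missing:
        raise KeyError(f"no window rates for individuals: {sorted(missing)}")
    ordered, table = _rate_table(rates_by_individual)

    def _stats(panel: set[str]):
        m = np.vstack([table[i] for i in sorted(panel)])
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(m, axis=0)
            lo = np.nanmin(m, axis=0)
            hi = np.nanmax(m, axis=0)
        # windows where any member is undefined give a partial mean (allowed)
        # but the min/max strict rule needs all members defined
        all_def = ~np.isnan(m).any(axis=0)
        lo[~all_def] = np.nan
        hi[~all_def] = np.nan
        return mean, lo, hi

    mean_a, min_a, max_a = _stats(set(panel_a))
    mean_b, min_b, max_b = _stats(set(panel_b))
    return PanelComparison(
        chrom_starts=ordered,
        mean_a=mean_a,
        mean_b=mean_b,
        min_a=min_a,
        max_a=max_a,
        min_b=min_b,
        max_b=max_b,
    )


@dataclass
class FlaggedRegion:
    chrom: str
    start: int
    end: int
    assembly: str  # which assembly shows the discordance
    label: str  # INTROGRESSION_CANDIDATE or SWITCH_CANDIDATE


def flag_discordant_regions(
    comparison_mat: PanelComparison, comparison_pat: PanelComparison, window: int = WINDOW
) -> list[FlaggedRegion]:
    """Label discordant window runs on the two assemblies.

    Both comparisons must be oriented with panel A = the assembly's own
    species (yak for the maternal assembly, cattle for the paternal).  A
    window is discordant on an assembly when every own-species individual
    has a strictly higher rate there than every other-species individual.
    Runs of discordant windows are merged; a region reciprocally discordant
    on the other assembly is a SWITCH_CANDIDATE (phasing alternated between
    haplotypes), otherwise an INTROGRESSION_CANDIDATE (one haplotype locally
    resembles the other species).
    """
    if comparison_mat.chrom_starts != comparison_pat.chrom_starts:
        raise ValueError("window grids of the two comparisons do not match")
    grid = comparison_mat.chrom_starts
    disc = {
        "maternal": comparison_mat.discordant_windows(),
        "paternal": comparison_pat.discordant_windows(),
    }
    regions: list[FlaggedRegion] = []
    for asm in ("maternal", "paternal"):
        other = "paternal" if asm == "maternal" else "maternal"
        mask = disc[asm]
        i = 0
        n = len(grid)
        while i < n:
            if not mask[i]:
                i += 1
                continue
            j = i
            chrom = grid[i][0]
            while j + 1 < n and mask[j + 1] and grid[j + 1][0] == chrom:
                j += 1
            reciprocal = bool(disc[other][i : j + 1].all())
            label = "SWITCH_CANDIDATE" if reciprocal else "INTROGRESSION_CANDIDATE"
            regions.append(
                FlaggedRegion(chrom, grid[i][1], grid[j][1] + window, asm, label)
            )
            i = j + 1
    return regions


def window_rates_frame(rates: list[WindowRate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (w.chrom, w.start, w.start + WINDOW, w.n_hom, w.n_het,
             w.n_genotyped_bases, w.rate)
            for w in rates
        ],
        columns=["chrom", "start", "end", "n_hom", "n_het", "n_genotyped", "rate"],
    )
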