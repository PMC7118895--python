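"""Window SNP rates, depth filtering, panel comparison, discordance flags."""

from __future__ import annotations

import numpy as np
import pytest

from triobin import io, phasing
from triobin.phasing import (
    HET,
    HOM_ALT,
    NOCALL,
    REF,
    SiteCall,
    WindowRate,
    call_site,
    compare_panels,
    compute_depth_bounds,
    flag_discordant_regions,
    window_snp_rates,
)


class TestDepthBounds:
    def test_constant_depth(self):
        assert compute_depth_bounds([30] * 100) == (30, 30)

    def test_uniform_1_to_1000(self):
        # symmetric nearest rank: 25th smallest and 25th largest
        assert compute_depth_bounds(range(1, 1001)) == (25, 976)

    def test_single_position(self):
        assert compute_depth_bounds([7]) == (7, 7)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            compute_depth_bounds([])


def _rec(bases, depth=None, pos=1):
    depth = len(bases) if depth is None else depth
    return io.PileupRecord("chr1", pos, "A", depth, bases, "I" * depth)


class TestCallSite:
    BOUNDS = (5, 100)

    def test_all_reference(self):
        assert call_site(_rec("." * 20), self.BOUNDS).call == REF

    def test_half_alt_is_het(self):
        assert call_site(_rec("." * 10 + "C" * 10), self.BOUNDS).call == HET

    def test_mostly_alt_is_hom(self):
        assert call_site(_rec("C" * 19 + "."), self.BOUNDS).call == HOM_ALT

    def test_below_depth_bound_nocall(self):
        assert call_site(_rec("...."), self.BOUNDS).call == NOCALL

    def test_malformed_column_nocall(self):
        rec = io.PileupRecord("chr1", 1, "A", 10, "..+x..", "I" * 10)
        assert call_site(rec, self.BOUNDS).call == NOCALL

    def test_mpileup_dialect_tokens(self):
        # start/end markers and indel annotations must not shift counts
        rec = io.PileupRecord("chr1", 1, "A", 8, "^I..$,+2AC,.C*", "I" * 8)
        n_ref, n_alt = io.pileup_base_counts(rec)
        assert (n_ref, n_alt) == (5, 1)


class TestWindowRates:
    def test_printed_formula_toy_value(self):
        calls = (
            [SiteCall("c", i + 1, 20, HOM_ALT) for i in range(2)]
            + [SiteCall("c", i + 10, 20, HET) for i in range(3)]
            + [SiteCall("c", i + 100, 20, REF) for i in range(39_995)]
        )
        (w,) = window_snp_rates(calls)
        assert w.n_genotyped_bases == 40_000
        assert w.rate == pytest.approx(8.75e-5)

    def test_zero_genotyped_window_flagged_undefined(self):
        calls = [SiteCall("c", 5, 1, NOCALL)]
        (w,) = window_snp_rates(calls)
        assert not w.defined and np.isnan(w.rate)

    def test_all_ref_rate_zero(self):
        calls = [SiteCall("c", i + 1, 20, REF) for i in range(100)]
        (w,) = window_snp_rates(calls)
        assert w.rate == 0.0

    def test_unsorted_input_rejected(self):
        calls = [SiteCall("c", 10, 20, REF), SiteCall("c", 5, 20, REF)]
        with pytest.raises(ValueError, match="unsorted"):
            window_snp_rates(calls)

    def test_chunk_invariance(self):
        rng = np.random.default_rng(3)
        calls = [
            SiteCall("c", int(p) + 1, 20, [REF, HET, HOM_ALT][rng.integers(3)])
            for p in sorted(rng.choice(200_000, size=5_000, replace=False))
        ]
        whole = window_snp_rates(calls)
        split = window_snp_rates(calls[:2_500]) + window_snp_rates(calls[2_500:])
        merged: dict = {}
        for w in split:
            key = (w.chrom, w.start)
            if key in merged:
                m = merged[key]
                merged[key] = WindowRate(
                    w.chrom, w.start, m.n_hom + w.n_hom, m.n_het + w.n_het,
                    m.n_genotyped_bases + w.n_genotyped_bases,
                )
            else:
                merged[key] = w
        assert {(w.chrom, w.start): w.rate for w in whole} == {
            k: w.rate for k, w in merged.items()
        }


def _rates(values: dict[int, float], chrom="c") -> list[WindowRate]:
    """WindowRate list with the given per-window rates (denominator 1e4)."""
    out = []
    for start, rate in values.items():
        n_hom = int(round(rate * 10_000))
        out.append(WindowRate(chrom, start * 50_000, n_hom, 0, 10_000))
    return out


class TestComparePanels:
    def test_uniformly_higher_panel(self):
        rates = {
            "a1": _rates({0: 0.01, 1: 0.02}),
            "a2": _rates({0: 0.011, 1: 0.021}),
            "b1": _rates({0: 0.001, 1: 0.002}),
        }
        comp = compare_panels(rates, {"a1", "a2"}, {"b1"})
        assert comp.fraction_a_higher == 1.0

    def test_identical_panels_undecided(self):
        rates = {"a1": _rates({0: 0.01}), "b1": _rates({0: 0.01})}
        comp = compare_panels(rates, {"a1"}, {"b1"})
        assert comp.decided.sum() == 0
        assert np.isnan(comp.fraction_a_higher)

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        rates = {
            name: _rates({i: float(r) for i, r in enumerate(rng.random(12) * 0.01)})
            for name in ("a1", "a2", "b1", "b2")
        }
        fwd = compare_panels(rates, {"a1", "a2"}, {"b1", "b2"})
        rev = compare_panels(rates, {"b1", "b2"}, {"a1", "a2"})
        assert fwd.decided.sum() == rev.decided.sum()
        assert fwd.fraction_a_higher == pytest.approx(1 - rev.fraction_a_higher)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            compare_panels({"a": _rates({0: 0.1})}, set(), {"a"})

    def test_undefined_windows_dropped_from_member_mean(self):
        rates = {
            "a1": _rates({0: 0.02}),
            "a2": [WindowRate("c", 0, 0, 0, 0)],  # undefined
            "b1": _rates({0: 0.01}),
        }
        comp = compare_panels(rates, {"a1", "a2"}, {"b1"})
        assert comp.mean_a[0] == pytest.approx(0.02)


class TestFlagDiscordantRegions:
    def _comparison(self, own: dict[int, list[float]], other: dict[int, list[float]]):
        rates = {}
        for i in range(len(next(iter(own.values())))):
            rates[f"own{i}"] = _rates({w: v[i] for w, v in own.items()})
        for i in range(len(next(iter(other.values())))):
            rates[f"oth{i}"] = _rates({w: v[i] for w, v in other.items()})
        return compare_panels(
            rates,
            {k for k in rates if k.startswith("own")},
            {k for k in rates if k.startswith("oth")},
        )

    def test_no_discordance_empty(self):
        normal = {w: [0.001, 0.0012] for w in range(6)}
        high = {w: [0.006, 0.0062] for w in range(6)}
        cm = self._comparison(normal, high)
        cp = self._comparison(normal, high)
        assert flag_discordant_regions(cm, cp) == []

    def test_introgression_label(self):
        own = {w: ([0.006, 0.0062] if w in (2, 3) else [0.001, 0.0012]) for w in range(6)}
        oth = {w: ([0.001, 0.0011] if w in (2, 3) else [0.006, 0.0061]) for w in range(6)}
        cm = self._comparison(own, oth)
        normal_own = {w: [0.001, 0.0012] for w in range(6)}
        normal_oth = {w: [0.006, 0.0062] for w in range(6)}
        cp = self._comparison(normal_own, normal_oth)
        regions = flag_discordant_regions(cm, cp)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.assembly, r.label) == (
            100_000, 200_000, "maternal", "INTROGRESSION_CANDIDATE",
        )

    def test_reciprocal_switch_label(self):
        own = {w: ([0.006] if w in (2, 3) else [0.001]) for w in range(6)}
        oth = {w: ([0.001] if w in (2, 3) else [0.006]) for w in range(6)}
        cm = self._comparison(own, oth)
        cp = self._comparison(own, oth)
        regions = flag_discordant_regions(cm, cp)
        assert {r.label for r in regions} == {"SWITCH_CANDIDATE"}

    def test_grid_mismatch_rejected(self):
        a = self._comparison({0: [0.1]}, {0: [0.2]})
        b = self._comparison({1: [0.1]}, {1: [0.2]})
        with pytest.raises(ValueError, match="grid"):
            flag_discordant_regions(a, b)
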