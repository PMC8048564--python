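"""Promoter windows, motif scanning, peak assignment and target calling."""

import re

import numpy as np
import pandas as pd
import pytest

from mlhgrn.dap import (
    call_direct_targets,
    peaks_to_genes,
    promoter_windows,
    reverse_complement,
    scan_motif,
)
from mlhgrn.interference import FrequencyTable
from mlhgrn.io import GeneModel, PeakSet, RunConfig


def _gene(gid="g", chrom="c", strand="+", tss=5000, is_tf=False):
    if strand == "+":
        return GeneModel(gid, chrom, strand, tss, tss, tss + 300, is_tf)
    return GeneModel(gid, chrom, strand, tss, tss - 299, tss + 1, is_tf)


class TestPromoterWindows:
    def test_plus_strand(self):
        w = promoter_windows([_gene()], 3000, 100, {"c": 10_000})[0]
        assert (w.start, w.end) == (2000, 5100)

    def test_minus_strand_mirror(self):
        w = promoter_windows([_gene(strand="-")], 3000, 100, {"c": 10_000})[0]
        assert (w.start, w.end) == (4901, 8001)

    def test_edge_clamp(self):
        w = promoter_windows([_gene(tss=50)], 3000, 100, {"c": 10_000})[0]
        assert (w.start, w.end) == (0, 150)

    def test_unknown_chromosome_named_in_error(self):
        with pytest.raises(KeyError, match="c"):
            promoter_windows([_gene()], 3000, 100, {"other": 1000})


class TestScanMotif:
    def _window(self, seq, gid="g"):
        from mlhgrn.dap import PromoterWindow

        return {"c": seq}, [PromoterWindow(gid, "c", 0, len(seq), "+")]

    def test_forward_hit(self):
        seqs, windows = self._window("AATGTCAGT")
        hits = scan_motif(seqs, windows, "TGTCAG")
        assert len(hits) == 1 and hits[0].position == 2 and hits[0].strand == "+"

    def test_reverse_hit(self):
        seqs, windows = self._window("GGCTGACAGG")
        hits = scan_motif(seqs, windows, "TGTCAG")
        assert len(hits) == 1 and hits[0].position == 2 and hits[0].strand == "-"

    def test_case_insensitive_and_n_never_matches(self):
        seqs, windows = self._window("aatgtcagtNNNNNN")
        assert len(scan_motif(seqs, windows, "TGTCAG")) == 1

    def test_matches_substring_oracle_on_random_windows(self, rng):
        """Hit counts equal an independent regex search, both strands, exactly."""
        motif = "TGTCAG"
        rc = reverse_complement(motif)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            seqs, windows = self._window(seq)
            got = len(scan_motif(seqs, windows, motif))
            want = len(re.findall(f"(?={motif})", seq)) + len(re.findall(f"(?={rc})", seq))
            assert got == want

    def test_strand_symmetry(self, rng):
        """Scanning the reverse-complemented genome mirrors the hit set."""
        motif = "TGTCAG"
        seq = "".join(rng.choice(list("ACGT"), size=500))
        seqs, windows = self._window(seq)
        fwd = scan_motif(seqs, windows, motif)
        seqs_rc, windows_rc = self._window(reverse_complement(seq))
        rev = scan_motif(seqs_rc, windows_rc, motif)
        assert len(fwd) == len(rev)
        got = sorted(len(seq) - h.position - len(motif) for h in rev)
        assert got == sorted(h.position for h in fwd)

    def test_window_outside_sequence_is_an_error(self):
        from mlhgrn.dap import PromoterWindow

        with pytest.raises(ValueError, match="bounds"):
            scan_motif({"c": "ACGT"}, [PromoterWindow("g", "c", 0, 10, "+")], "TGTCAG")


class TestPeaksToGenes:
    def _windows(self):
        from mlhgrn.dap import PromoterWindow

        return [PromoterWindow("g", "c", 2000, 5100, "+")]

    @pytest.mark.parametrize(
        "peak, assigned",
        [
            ((5050, 5150), True),   # 50 bp overlap
            ((5100, 5200), False),  # half-open boundary: no overlap
        ],
    )
    def test_boundary_rules(self, peak, assigned):
        peaks = PeakSet([("c", *peak, 1.0)], "r")
        has_peak, table = peaks_to_genes(peaks, self._windows())
        assert has_peak["g"] is assigned
        assert (table["genes"] != "intergenic").iloc[0] is np.bool_(assigned)

    def test_peak_spanning_two_windows_assigned_to_both(self):
        from mlhgrn.dap import PromoterWindow

        windows = [
            PromoterWindow("a", "c", 0, 1000, "+"),
            PromoterWindow("b", "c", 900, 2000, "+"),
        ]
        peaks = PeakSet([("c", 950, 980, 1.0)], "r")
        has_peak, table = peaks_to_genes(peaks, windows)
        assert has_peak == {"a": True, "b": True}
        assert set(table["genes"].iloc[0].split(",")) == {"a", "b"}

    def test_translation_invariance(self, rng):
        from mlhgrn.dap import PromoterWindow

        starts = rng.integers(0, 5000, 20)
        windows = [PromoterWindow(f"g{i}", "c", int(s), int(s) + 400, "+") for i, s in enumerate(starts)]
        peaks = PeakSet([("c", int(s), int(s) + 150, 1.0) for s in rng.integers(0, 5000, 15)], "r")
        base, _ = peaks_to_genes(peaks, windows)
        shift = 10_000
        windows2 = [PromoterWindow(w.gene_id, "c", w.start + shift, w.end + shift, "+") for w in windows]
        peaks2 = PeakSet([("c", s + shift, e + shift, v) for (_, s, e, v) in peaks.peaks], "r")
        moved, _ = peaks_to_genes(peaks2, windows2)
        assert base == moved


class TestCallDirectTargets:
    def _freq(self, entries):
        frame = pd.DataFrame(
            {
                "gene_id": list(entries),
                "n_significant_pairs": [int(f * 10) for f in entries.values()],
                "n_pairs": 10,
                "frequency": list(entries.values()),
            }
        )
        frame["rank"] = frame["frequency"].rank(ascending=False, method="min").astype(int)
        return FrequencyTable(frame)

    def test_conjunction_rule(self):
        freq = self._freq({"a": 0.9, "b": 0.9, "c": 0.1, "d": 0.2})
        genes = [_gene(g) for g in "abcd"]
        calls = {
            c.gene_id: c
            for c in call_direct_targets(
                freq, {"a": True, "b": True}, type("H", (), {})() and [], genes
            )
        }
        # no motif evidence at all: nothing selected
        assert not any(c.selected for c in calls.values())

    def test_peak_and_motif_both_required(self):
        from mlhgrn.dap import MotifHit

        freq = self._freq({"a": 0.9, "b": 0.9, "c": 0.1, "d": 0.1})
        genes = [_gene(g) for g in "abcd"]
        hits = [MotifHit("c", 0, "+", "a")]
        calls = {
            c.gene_id: c
            for c in call_direct_targets(freq, {"a": True, "b": True}, hits, genes)
        }
        assert calls["a"].selected          # frequency + peak + motif
        assert not calls["b"].selected      # peak but no motif
        assert not calls["c"].selected      # below cutoff

    def test_removing_evidence_only_removes(self):
        from mlhgrn.dap import MotifHit

        freq = self._freq({"a": 0.9, "b": 0.8, "c": 0.1, "d": 0.1})
        genes = [_gene(g) for g in "abcd"]
        hits = [MotifHit("c", 0, "+", "a"), MotifHit("c", 9, "+", "b")]
        full = {c.gene_id for c in call_direct_targets(freq, {"a": True, "b": True}, hits, genes) if c.selected}
        dropped = {c.gene_id for c in call_direct_targets(freq, {"a": True}, hits, genes) if c.selected}
        assert dropped <= full and "b" not in dropped

    def test_all_zero_frequencies_warns_and_selects_nothing(self, caplog):
        freq = self._freq({"a": 0.0, "b": 0.0})
        with caplog.at_level("WARNING"):
            calls = call_direct_targets(freq, {"a": True}, [], [_gene("a"), _gene("b")])
        assert not any(c.selected for c in calls)
        assert "zero" in caplog.text

    def test_is_tf_copied_from_gene_models(self):
        from mlhgrn.dap import MotifHit

        freq = self._freq({"a": 0.9, "b": 0.2, "c": 0.1, "d": 0.1})
        genes = [_gene("a", is_tf=True)] + [_gene(g) for g in "bcd"]
        calls = {c.gene_id: c for c in call_direct_targets(
            freq, {"a": True}, [MotifHit("c", 0, "+", "a")], genes)}
        assert calls["a"].is_tf and not calls["b"].is_tf
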