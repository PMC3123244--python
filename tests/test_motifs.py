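"""Promoter extraction, PWM scanning and Fisher enrichment against oracles."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from netanim.motifs import (
    MotifMatrix,
    extract_upstream,
    overrepresentation,
    read_meme_motifs,
    revcomp,
    scan_pwm,
)

BASES = "ACGT"


def make_motif(consensus, p_major=0.85, bg=None, name="m"):
    rows = []
    minor = (1 - p_major) / 3
    for base in consensus:
        row = [minor] * 4
        row[BASES.index(base)] = p_major
        rows.append(row)
    return MotifMatrix(name, np.array(rows), np.full(4, 0.25) if bg is None else np.asarray(bg))


def scan_oracle(seq, motif, threshold):
    """Per-window log-odds summation, coded independently of the scanner."""
    hits = []
    w = motif.length
    for pos in range(len(seq) - w + 1):
        window = seq[pos : pos + w]
        if any(b not in BASES for b in window):
            continue
        fwd = sum(
            math.log2(motif.probs[i][BASES.index(b)] / motif.background[BASES.index(b)])
            for i, b in enumerate(window)
        )
        rc = revcomp(window)
        rev = sum(
            math.log2(motif.probs[i][BASES.index(b)] / motif.background[BASES.index(b)])
            for i, b in enumerate(rc)
        )
        if fwd >= threshold:
            hits.append((pos + 1, "+", fwd))
        if rev >= threshold:
            hits.append((pos + 1, "-", rev))
    return hits


def fisher_oracle(fg_hit, fg_total, bg_hit, bg_total):
    """One-sided (enrichment) Fisher p as an exact hypergeometric tail sum."""
    n = fg_total + bg_total
    k = fg_hit + bg_hit  # total hits
    p = 0.0
    for x in range(fg_hit, min(k, fg_total) + 1):
        if k - x > bg_total:
            continue
        p += comb(fg_total, x) * comb(bg_total, k - x) / comb(n, k)
    return p


class TestExtractUpstream:
    GENOME = {"chrI": "ACGT" * 500}  # 2000 nt

    def _coords(self, rows):
        return pd.DataFrame(rows, columns=["contig", "tss", "strand", "gene"])

    def test_plus_strand_takes_bases_upstream(self):
        coords = self._coords([("chrI", 1001, "+", "g1")])
        out = extract_upstream(self.GENOME, coords, length=1000)
        assert out["g1"] == self.GENOME["chrI"][:1000]

    def test_minus_strand_reverse_complements_downstream(self):
        coords = self._coords([("chrI", 5, "-", "g1")])
        out = extract_upstream(self.GENOME, coords, length=1000)
        assert out["g1"] == revcomp(self.GENOME["chrI"][5:1005])

    def test_truncated_at_contig_start(self):
        coords = self._coords([("chrI", 500, "+", "g1")])
        out = extract_upstream(self.GENOME, coords, length=1000)
        assert out["g1"] == self.GENOME["chrI"][:499]
        assert len(out["g1"]) == 499

    def test_tss_off_contig_names_gene(self):
        coords = self._coords([("chrI", 5000, "+", "gBad")])
        with pytest.raises(ValueError, match="gBad"):
            extract_upstream(self.GENOME, coords)


class TestScanPwm:
    def test_consensus_sequence_scores_maximum_at_position_one(self):
        motif = make_motif("ACGTG")
        hits = scan_pwm("ACGTG", motif)
        fwd = [h for h in hits if h[1] == "+"]
        assert fwd[0][0] == 1
        assert fwd[0][2] == pytest.approx(motif.max_score)

    def test_all_n_sequence_has_no_hits(self):
        assert scan_pwm("N" * 50, make_motif("ACGT")) == []

    def test_motif_longer_than_sequence_is_empty(self):
        assert scan_pwm("ACG", make_motif("ACGTACGT")) == []

    def test_random_sequence_matches_window_oracle(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list(BASES), size=30))
        motif = make_motif("AGGGG", bg=[0.31, 0.19, 0.19, 0.31])
        threshold = 0.0  # report every window, both strands
        got = scan_pwm(seq, motif, threshold)
        expected = scan_oracle(seq, motif, threshold)
        assert len(got) == len(expected)
        for (gp, gs, gv), (ep, es, ev) in zip(sorted(got), sorted(expected)):
            assert (gp, gs) == (ep, es)
            assert gv == pytest.approx(ev, abs=1e-9)

    def test_strand_symmetry(self):
        """Scanning the reverse complement swaps strands, keeps the score multiset."""
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list(BASES), size=60))
        motif = make_motif("ACGGT")
        fwd_scores = sorted(s for _, _, s in scan_pwm(seq, motif, -50.0))
        rev_scores = sorted(s for _, _, s in scan_pwm(revcomp(seq), motif, -50.0))
        assert fwd_scores == pytest.approx(rev_scores)


class TestMemeParsing:
    MEME = """MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.31 C 0.19 G 0.19 T 0.31

MOTIF M1
letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0
0.94 0.02 0.02 0.02
0.02 0.02 0.94 0.02
0.02 0.02 0.94 0.02
"""

    def test_probabilities_normalized_no_zeros(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(self.MEME)
        (motif,) = read_meme_motifs(p)
        assert motif.length == 3
        assert np.allclose(motif.probs.sum(axis=1), 1.0)
        assert (motif.probs > 0).all()
        assert motif.background == pytest.approx([0.31, 0.19, 0.19, 0.31])


class TestOverrepresentation:
    def test_equal_fractions_give_unit_ratio(self):
        motif = make_motif("AAAAAA", p_major=0.97)
        fg = {"f1": "AAAAAA" + "C" * 20, "f2": "G" * 26}
        bg = {"b1": "AAAAAA" + "C" * 20, "b2": "G" * 26}
        table = overrepresentation(fg, bg, [motif])
        assert table["ratio"].iloc[0] == pytest.approx(1.0)

    def test_fisher_p_matches_hypergeometric_tail(self):
        """fg 10/10 hit vs bg 10/100 hit: ratio 10, p equals the tail sum."""
        motif = make_motif("AAAAAA", p_major=0.97)
        fg = {f"f{i}": "AAAAAA" + "C" * 10 for i in range(10)}
        bg = {f"b{i}": ("AAAAAA" if i < 10 else "GCGCGC") + "C" * 10 for i in range(100)}
        table = overrepresentation(fg, bg, [motif]).set_index("motif_id")
        assert table.loc["m", "ratio"] == pytest.approx(10.0)
        assert table.loc["m", "p"] == pytest.approx(fisher_oracle(10, 10, 10, 100), abs=1e-12)

    def test_fisher_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(3)
        import scipy.stats as st

        for _ in range(25):
            fg_total = int(rng.integers(5, 30))
            bg_total = int(rng.integers(20, 120))
            fg_hit = int(rng.integers(0, fg_total + 1))
            bg_hit = int(rng.integers(0, bg_total + 1))
            _, p = st.fisher_exact(
                [[fg_hit, fg_total - fg_hit], [bg_hit, bg_total - bg_hit]],
                alternative="greater",
            )
            assert p == pytest.approx(fisher_oracle(fg_hit, fg_total, bg_hit, bg_total), abs=1e-12)

    def test_motif_absent_everywhere_dropped(self):
        motif = make_motif("AAAAAA", p_major=0.97)
        table = overrepresentation({"f": "G" * 20}, {"b": "G" * 20}, [motif])
        assert len(table) == 0

    def test_zero_background_fraction_sorts_first_with_infinite_ratio(self):
        present = make_motif("AAAAAA", p_major=0.97, name="fg_only")
        common = make_motif("GGGGGG", p_major=0.97, name="common")
        fg = {"f": "AAAAAAGGGGGG"}
        bg = {"b1": "GGGGGGCCCCCC", "b2": "GGGGGGCCCCCC"}
        table = overrepresentation(fg, bg, [common, present])
        assert table["motif_id"].iloc[0] == "fg_only"
        assert math.isinf(table["ratio"].iloc[0])

    def test_planted_motif_ranks_first(self):
        """Foreground promoters carrying the planted motif rank it top by ratio."""
        rng = np.random.default_rng(4)
        planted = make_motif("AAGGGGCG", p_major=0.94, name="planted")
        decoys = [make_motif(c, p_major=0.94, name=f"decoy_{c}") for c in ("ACACACAC", "TTGCAATT")]

        def random_seq(n=200):
            return "".join(rng.choice(list(BASES), size=n, p=[0.31, 0.19, 0.19, 0.31]))

        fg = {}
        for i in range(20):
            s = random_seq()
            pos = int(rng.integers(0, len(s) - 8))
            fg[f"f{i}"] = s[:pos] + "AAGGGGCG" + s[pos + 8:]
        bg = {f"b{i}": random_seq() for i in range(100)}
        table = overrepresentation(fg, bg, decoys + [planted])
        assert table["motif_id"].iloc[0] == "planted"
        assert table["ratio"].iloc[0] == table["ratio"].max()
        top = table.iloc[0]
        assert top["fg_fraction"] == 1.0
        assert top["p_adj"] == table["p_adj"].min()
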