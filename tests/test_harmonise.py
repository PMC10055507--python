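import numpy as np
import pandas as pd
import pytest

from mrphewas import harmonise
from mrphewas.harmonise import RETAINED_STATUSES, complement, is_palindromic
from mrphewas.sumstats import InstrumentSet

from conftest import make_table


def _iset(rows):
    t = make_table(rows)
    df = t.df.copy()
    df["f_stat"] = (df["beta"] / df["se"]) ** 2
    return InstrumentSet(trait_id="exp", trait_type="continuous", df=df)


def _pair(exp_alleles, out_alleles, eaf_exp=0.3, eaf_out=0.3, beta_out=0.1):
    exp = _iset([{"variant_id": "rs1", "effect_allele": exp_alleles[0],
                  "other_allele": exp_alleles[1], "eaf": eaf_exp,
                  "beta": 0.2, "se": 0.01}])
    out = make_table([{"variant_id": "rs1", "effect_allele": out_alleles[0],
                       "other_allele": out_alleles[1], "eaf": eaf_out,
                       "beta": beta_out, "se": 0.02}], trait_id="out",
                     trait_type="binary")
    return exp, out


class TestAlleleLogic:
    def test_complement_and_palindrome_detection(self):
        assert complement("A") == "T" and complement("AG") == "CT"
        assert is_palindromic("A", "T") and is_palindromic("C", "G")
        assert not is_palindromic("A", "G")

    def test_matching_alleles_left_aligned(self):
        h = harmonise(*_pair(("A", "G"), ("A", "G"), beta_out=0.1))
        row = h.df.iloc[0]
        assert row["status"] == "aligned" and row["beta_out"] == 0.1

    def test_swapped_alleles_flip_sign_and_frequency(self):
        h = harmonise(*_pair(("A", "G"), ("G", "A"), eaf_out=0.7, beta_out=0.1))
        row = h.df.iloc[0]
        assert row["status"] == "flipped"
        assert row["beta_out"] == pytest.approx(-0.1)
        assert row["eaf_out"] == pytest.approx(0.3)

    def test_strand_flip_resolved_by_complementing(self):
        # A/G on one strand is T/C on the other
        h = harmonise(*_pair(("A", "G"), ("T", "C"), beta_out=0.1))
        assert h.df.iloc[0]["status"] == "aligned"
        h = harmonise(*_pair(("A", "G"), ("C", "T"), beta_out=0.1))
        row = h.df.iloc[0]
        assert row["status"] == "flipped" and row["beta_out"] == pytest.approx(-0.1)

    def test_incompatible_alleles_dropped(self):
        h = harmonise(*_pair(("A", "G"), ("A", "C")))
        assert len(h) == 0 and h.drops == {"dropped_incompatible": 1}

    def test_missing_outcome_variant_counted(self):
        exp, out = _pair(("A", "G"), ("A", "G"))
        out.df["variant_id"] = ["rs_other"]
        h = harmonise(exp, out)
        assert len(h) == 0 and h.drops == {"dropped_missing_outcome": 1}


class TestPalindromes:
    @pytest.mark.parametrize("eaf_exp,eaf_out,window", [
        (0.49, 0.49, 0.08), (0.3, 0.45, 0.08), (0.45, 0.3, 0.08), (0.5, 0.5, 0.08),
    ])
    def test_ambiguous_frequencies_dropped(self, eaf_exp, eaf_out, window):
        h = harmonise(*_pair(("A", "T"), ("A", "T"), eaf_exp, eaf_out), window)
        assert h.drops == {"dropped_palindromic": 1}

    def test_missing_frequency_dropped(self):
        h = harmonise(*_pair(("A", "T"), ("A", "T"), eaf_exp=np.nan, eaf_out=0.2))
        assert h.drops == {"dropped_palindromic": 1}

    def test_concordant_frequencies_kept(self):
        h = harmonise(*_pair(("A", "T"), ("A", "T"), 0.2, 0.25, beta_out=0.1))
        row = h.df.iloc[0]
        assert row["status"] == "palindromic_kept" and row["beta_out"] == 0.1

    def test_discordant_frequencies_reoriented(self):
        h = harmonise(*_pair(("A", "T"), ("A", "T"), 0.2, 0.75, beta_out=0.1))
        row = h.df.iloc[0]
        assert row["status"] == "palindromic_kept"
        assert row["beta_out"] == pytest.approx(-0.1)
        assert row["eaf_out"] == pytest.approx(0.25)

    def test_window_rule_matches_independent_oracle(self):
        # enumerate an eaf grid and compare against a direct restatement of
        # the rule: keep iff both frequencies are at least w from 0.5
        w = 0.08
        grid = np.round(np.arange(0.05, 0.96, 0.05), 2)
        for ex in grid:
            for eo in grid:
                h = harmonise(*_pair(("C", "G"), ("C", "G"), ex, eo), w)
                kept = len(h) == 1
                assert kept == (abs(ex - 0.5) >= w and abs(eo - 0.5) >= w)


class TestInvariants:
    def _random_pair(self, rng, n=12):
        pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("A", "T")]
        rows_e, rows_o = [], []
        for i in range(n):
            ea, oa = pairs[rng.integers(len(pairs))]
            eaf = float(rng.uniform(0.05, 0.95))
            rows_e.append({"variant_id": f"rs{i}", "effect_allele": ea,
                           "other_allele": oa, "eaf": eaf,
                           "beta": float(rng.normal(0, 0.1)), "se": 0.01})
            swap = rng.random() < 0.5
            rows_o.append({"variant_id": f"rs{i}",
                           "effect_allele": oa if swap else ea,
                           "other_allele": ea if swap else oa,
                           "eaf": (1 - eaf) if swap else eaf,
                           "beta": float(rng.normal(0, 0.1)), "se": 0.02})
        return _iset(rows_e), make_table(rows_o, trait_id="out", trait_type="binary")

    def test_counts_conserved(self, rng):
        exp, out = self._random_pair(rng)
        h = harmonise(exp, out)
        assert len(h) + sum(h.drops.values()) == len(exp)
        assert set(h.df["status"]) <= set(RETAINED_STATUSES)

    def test_harmonising_twice_is_noop(self, rng):
        exp, out = self._random_pair(rng)
        h1 = harmonise(exp, out)
        # rebuild exposure/outcome tables from the harmonised output
        exp2 = _iset([{"variant_id": v, "effect_allele": "A", "other_allele": "G",
                       "eaf": e, "beta": b, "se": s}
                      for v, b, s, e in zip(h1.df["variant_id"], h1.df["beta_exp"],
                                            h1.df["se_exp"], h1.df["eaf_exp"])])
        out2 = make_table([{"variant_id": v, "effect_allele": "A", "other_allele": "G",
                            "eaf": e, "beta": b, "se": s}
                           for v, b, s, e in zip(h1.df["variant_id"], h1.df["beta_out"],
                                                 h1.df["se_out"], h1.df["eaf_out"])],
                          trait_id="out", trait_type="binary")
        h2 = harmonise(exp2, out2)
        np.testing.assert_allclose(h2.df["beta_out"], h1.df["beta_out"])
        np.testing.assert_allclose(h2.df["beta_exp"], h1.df["beta_exp"])

    def test_double_allele_flip_leaves_products_invariant(self, rng):
        exp, out = self._random_pair(rng)
        h1 = harmonise(exp, out)
        ref1 = dict(zip(h1.df["variant_id"], h1.df["beta_exp"] * h1.df["beta_out"]))

        def _flip_table(df):
            df = df.copy()
            df[["effect_allele", "other_allele"]] = df[["other_allele", "effect_allele"]].to_numpy()
            df["beta"] = -df["beta"]
            df["eaf"] = 1 - df["eaf"]
            return df

        exp_f = InstrumentSet("exp", "continuous", _flip_table(exp.df))
        out_f = make_table(_flip_table(out.df), trait_id="out", trait_type="binary")
        h2 = harmonise(exp_f, out_f)
        ref2 = dict(zip(h2.df["variant_id"], h2.df["beta_exp"] * h2.df["beta_out"]))
        assert set(ref1) == set(ref2)
        for v in ref1:
            assert ref1[v] == pytest.approx(ref2[v])
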