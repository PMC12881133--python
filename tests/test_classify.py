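"""Sustained selection and responder-set algebra, incl. brute-force oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import sustaindeg as sd
from sustaindeg.classify import RESPONDER_LABELS, SUSTAINED_STATUSES
from sustaindeg.fixtures import sustained_calls_from_marginals

DIRS = ("up", "down", "ns")


def calls(genes_dirs: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"direction": list(genes_dirs.values())},
        index=pd.Index(list(genes_dirs.keys()), name="gene_id"),
    )


def status_table(statuses: dict[str, str], stimulus: str) -> pd.DataFrame:
    return pd.DataFrame(
        {"stimulus": stimulus, "status": list(statuses.values())},
        index=pd.Index(list(statuses.keys()), name="gene_id"),
    )


# ---------------------------------------------------------------------------
# independent brute-force oracle, straight from the definitions
# ---------------------------------------------------------------------------

def oracle_status(d1: str, d2: str) -> str:
    if d1 == d2 and d1 in ("up", "down"):
        return d1
    if {d1, d2} == {"up", "down"}:
        return "inconsistent"
    return "not_sustained"


def oracle_label(dl12: str, dl24: str, di12: str, di24: str) -> str:
    L = oracle_status(dl12, dl24)
    I = oracle_status(di12, di24)
    sus_l, sus_i = L in ("up", "down"), I in ("up", "down")
    if sus_l and sus_i:
        if L == I:
            return f"common_{L}"
        return "opposite_lps_up_il4_down" if L == "up" else "opposite_il4_up_lps_down"
    if (sus_l and I == "inconsistent") or (sus_i and L == "inconsistent"):
        return "ambiguous"
    if sus_l:
        return f"lps_specific_{L}"
    if sus_i:
        return f"il4_specific_{I}"
    if L == "inconsistent" or I == "inconsistent":
        return "ambiguous"
    return "none"


# ---------------------------------------------------------------------------
# sustained selection
# ---------------------------------------------------------------------------

class TestCallSustained:
    @pytest.mark.parametrize(
        "d12,d24,expected",
        [
            ("up", "up", "up"),
            ("down", "down", "down"),
            ("down", "up", "inconsistent"),  # the F5-like flip
            ("up", "down", "inconsistent"),  # the Fabp3-like flip
            ("up", "ns", "not_sustained"),
            ("ns", "down", "not_sustained"),
            ("ns", "ns", "not_sustained"),
        ],
    )
    def test_definition(self, d12, d24, expected):
        out = sd.call_sustained(calls({"g": d12}), calls({"g": d24}), "LPS")
        assert out.loc["g", "status"] == expected

    def test_universe_mismatch_is_error(self):
        with pytest.raises(ValueError, match="universe"):
            sd.call_sustained(
                calls({"g1": "up"}), calls({"g1": "up", "g2": "ns"}), "LPS"
            )


# ---------------------------------------------------------------------------
# responder classification
# ---------------------------------------------------------------------------

class TestClassifyResponders:
    def test_exhaustive_agreement_with_brute_force(self):
        """One gene per direction 4-tuple (81 genes) classified through the
        pipeline matches the independent oracle applied to the raw tuple."""
        combos = list(itertools.product(DIRS, repeat=4))
        ids = [f"g{i}" for i in range(len(combos))]
        l12 = calls(dict(zip(ids, (c[0] for c in combos))))
        l24 = calls(dict(zip(ids, (c[1] for c in combos))))
        i12 = calls(dict(zip(ids, (c[2] for c in combos))))
        i24 = calls(dict(zip(ids, (c[3] for c in combos))))
        got = sd.classify_responders(
            sd.call_sustained(l12, l24, "LPS"), sd.call_sustained(i12, i24, "IL4")
        )
        for gid, combo in zip(ids, combos):
            assert got.loc[gid, "label"] == oracle_label(*combo), combo

    def test_ambiguous_gene_excluded_from_common_and_specific(self):
        """Sustained down under IL-4 + inconsistent under LPS -> ambiguous
        (the rule that turns 166 - 75 into 90, not 91)."""
        s_lps = status_table({"fabp3": "inconsistent"}, "LPS")
        s_il4 = status_table({"fabp3": "down"}, "IL4")
        cls = sd.classify_responders(s_lps, s_il4)
        assert cls.loc["fabp3", "label"] == "ambiguous"
        summary = sd.summarize_sets(cls, s_lps, s_il4)
        assert summary["common_down"] == 0
        assert summary["il4_specific_down"] == 0
        assert summary["ambiguous"] == 1

    def test_opposite_gene_label_and_go_allocation(self):
        s_lps = status_table({"sw": "up"}, "LPS")
        s_il4 = status_table({"sw": "down"}, "IL4")
        cls = sd.classify_responders(s_lps, s_il4)
        assert cls.loc["sw", "label"] == "opposite_lps_up_il4_down"
        lists = sd.build_go_inputs(cls)
        assert "sw" in lists["LPSup"] and "sw" in lists["IL4down"]
        assert "sw" not in lists["LPSdown"] and "sw" not in lists["IL4up"]

    def test_double_not_sustained_is_none(self):
        cls = sd.classify_responders(
            status_table({"g": "not_sustained"}, "LPS"),
            status_table({"g": "not_sustained"}, "IL4"),
        )
        assert cls.loc["g", "label"] == "none"

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(SUSTAINED_STATUSES), st.sampled_from(SUSTAINED_STATUSES)
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_partition_and_summary_identities(self, pairs):
        ids = [f"g{i}" for i in range(len(pairs))]
        s_lps = status_table(dict(zip(ids, (p[0] for p in pairs))), "LPS")
        s_il4 = status_table(dict(zip(ids, (p[1] for p in pairs))), "IL4")
        cls = sd.classify_responders(s_lps, s_il4)
        # partition: one known label per gene, counts sum to the universe
        assert set(cls["label"]) <= set(RESPONDER_LABELS)
        assert cls["label"].value_counts().sum() == len(ids)
        # set identities: specific = sustained - common - ambiguous-in-direction
        summary = sd.summarize_sets(cls, s_lps, s_il4)
        for stim, s_own, s_other in (("lps", s_lps, s_il4), ("il4", s_il4, s_lps)):
            for direction in ("up", "down"):
                sustained = int((s_own["status"] == direction).sum())
                ambiguous_dir = int(
                    (
                        (s_own["status"] == direction)
                        & (s_other["status"] == "inconsistent")
                    ).sum()
                )
                assert (
                    summary[f"{stim}_specific_{direction}"]
                    == sustained - summary[f"common_{direction}"] - ambiguous_dir
                )

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(SUSTAINED_STATUSES), st.sampled_from(SUSTAINED_STATUSES)
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_stimulus_swap_symmetry(self, pairs):
        ids = [f"g{i}" for i in range(len(pairs))]
        s_lps = status_table(dict(zip(ids, (p[0] for p in pairs))), "LPS")
        s_il4 = status_table(dict(zip(ids, (p[1] for p in pairs))), "IL4")
        fwd = sd.summarize_sets(
            sd.classify_responders(s_lps, s_il4), s_lps, s_il4
        )
        swapped_lps = s_il4.assign(stimulus="LPS")
        swapped_il4 = s_lps.assign(stimulus="IL4")
        rev = sd.summarize_sets(
            sd.classify_responders(swapped_lps, swapped_il4), swapped_lps, swapped_il4
        )
        for direction in ("up", "down"):
            assert fwd[f"lps_specific_{direction}"] == rev[f"il4_specific_{direction}"]
            assert fwd[f"common_{direction}"] == rev[f"common_{direction}"]
        assert (
            fwd["opposite_lps_up_il4_down"] == rev["opposite_il4_up_lps_down"]
        )
        assert fwd["ambiguous"] == rev["ambiguous"]

    def test_universe_mismatch_is_error(self):
        with pytest.raises(ValueError, match="universe"):
            sd.classify_responders(
                status_table({"g1": "up"}, "LPS"), status_table({"g2": "up"}, "IL4")
            )


# ---------------------------------------------------------------------------
# published-count fixture: set sizes and tallies
# ---------------------------------------------------------------------------

class TestPublishedSetAlgebra:
    @pytest.fixture(scope="class")
    def published(self):
        s_lps, s_il4 = sustained_calls_from_marginals(
            sustained_lps_up=882,
            sustained_lps_down=606,
            sustained_il4_up=235,
            sustained_il4_down=166,
            common_up=73,
            common_down=75,
            opp_lps_up_il4_down=24,
            opp_il4_up_lps_down=21,
            n_lps_flip=3,
            n_ambiguous_il4_down=1,
            n_null=100,
        )
        cls = sd.classify_responders(s_lps, s_il4)
        return s_lps, s_il4, cls

    def test_specific_and_opposite_counts(self, published):
        s_lps, s_il4, cls = published
        summary = sd.summarize_sets(cls, s_lps, s_il4)
        assert summary["lps_specific_up"] == 809
        assert summary["lps_specific_down"] == 531
        assert summary["il4_specific_up"] == 162
        assert summary["il4_specific_down"] == 90
        assert summary["opposite_total"] == 45
        assert summary["common_up"] == 73
        assert summary["common_down"] == 75

    def test_venn_tallies_count_flips_twice(self, published):
        s_lps, s_il4, _ = published
        venn = sd.venn_tallies(s_lps, s_il4)
        assert venn["lps_up"] == 886
        assert venn["lps_down"] == 610
        assert venn["il4_up"] == 235
        assert venn["il4_down"] == 166

    def test_go_input_sizes_match_specific_counts(self, published):
        s_lps, s_il4, cls = published
        lists = sd.build_go_inputs(cls)
        assert len(lists["LPSup"]) == 809
        assert len(lists["LPSdown"]) == 531
        assert len(lists["IL4up"]) == 162
        assert len(lists["IL4down"]) == 90
        common = set(cls.index[cls["label"].isin(["common_up", "common_down"])])
        for gene_list in lists.values():
            assert not common & set(gene_list)


# ---------------------------------------------------------------------------
# truth recovery on simulated data
# ---------------------------------------------------------------------------

LABEL_TO_CLASS = {
    "lps_up": "lps_specific_up",
    "lps_down": "lps_specific_down",
    "il4_up": "il4_specific_up",
    "il4_down": "il4_specific_down",
    "common_up": "common_up",
    "common_down": "common_down",
    "opp_lps_up_il4_down": "opposite_lps_up_il4_down",
    "opp_il4_up_lps_down": "opposite_il4_up_lps_down",
}


class TestTruthRecovery:
    def test_well_expressed_planted_genes_recovered(self, default_sim, default_result):
        """Planted responder genes above the low-expression detectability
        floor (baseline >= ~60 counts) recover their class >= 90% of the time;
        genome-wide recovery under the default baseline distribution is
        reported by the acceptance suite."""
        cm, truth = default_sim
        t = truth.set_index("gene_id")
        cls = default_result.classes["label"]
        planted = t[t["label"].isin(LABEL_TO_CLASS) & (t["baseline_mean"] >= 60)]
        assert len(planted) > 100
        hits = np.mean(
            [cls.loc[g] == LABEL_TO_CLASS[t.loc[g, "label"]] for g in planted.index]
        )
        assert hits >= 0.90

    def test_flip_genes_never_called_common(self, default_sim, default_result):
        _, truth = default_sim
        t = truth.set_index("gene_id")
        flips = t.index[t["label"].isin(["flip_lps", "flip_il4"])]
        labels = default_result.classes.loc[flips, "label"]
        assert not labels.isin(["common_up", "common_down"]).any()

    def test_transient_genes_not_sustained(self, default_sim, default_result):
        _, truth = default_sim
        t = truth.set_index("gene_id")
        transient = t.index[t["label"].str.startswith("transient")]
        labels = default_result.classes.loc[transient, "label"]
        # a transient response is by construction not sustained anywhere
        assert (labels == "none").mean() >= 0.95
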