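"""Rule-based ZGA calling: floored ratios, rulesets, fold change, merging."""

import numpy as np
import pandas as pd
import pytest

from zgakit.expression import (
    NON_ZGA,
    RULESETS,
    UNASSIGNED,
    ZGA,
    CallResult,
    Condition,
    SpeciesRuleset,
    StageExpressionTable,
    call_non_zga,
    call_zga,
    floored_ratio,
    fold_change,
    merge_candidates,
)

MOUSE = RULESETS["mouse"]


def make_table(rows: dict, stages=MOUSE.stages, species="mouse"):
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(stages), dtype=float)
    return StageExpressionTable(species=species, values=df)


class TestFlooredRatio:
    @pytest.mark.parametrize(
        "num,den,floor,expected",
        [(10, 0.1, 0.5, 20.0), (3, 1.0, 0.5, 3.0), (0, 0, 0.5, 0.0)],
    )
    def test_values(self, num, den, floor, expected):
        assert floored_ratio(num, den, floor) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            floored_ratio(-1, 1, 0.5)
        with pytest.raises(ValueError):
            floored_ratio(1, 1, 0.0)


class TestCallZga:
    def test_low_maternal_early2c_fires(self):
        # 5 / max(0.1, 0.5) = 10 > 2.5 fires the early2C/1C rule
        table = make_table({"g1": [0.1, 0.1, 5, 0.1, 0.1, 0.1, 0.1, 0.1]})
        res = call_zga(table, MOUSE)
        assert res.labels["g1"] == ZGA
        assert any(r.startswith("early2C/1C") for r in res.fired_rules["g1"])

    def test_all_zero_not_zga(self):
        table = make_table({"g1": [0] * 8})
        res = call_zga(table, MOUSE)
        assert res.labels["g1"] == NON_ZGA  # sums to 0 < 2

    def test_subthreshold_ratio_does_not_fire(self):
        # early2C/1C = 20/10 = 2.0 <= 2.5; but late2C/early2C also at play:
        # keep late stages flat so nothing else fires
        table = make_table({"g1": [10, 10, 20, 20, 0, 0, 0, 0]})
        res = call_zga(table, MOUSE)
        assert "g1" not in res.fired_rules
        assert res.labels["g1"] == UNASSIGNED  # sum 50 >= 2, no rule fired

    def test_missing_stage_raises_with_name(self):
        df = pd.DataFrame({"MII": [1.0]}, index=["g1"])
        table = StageExpressionTable(species="mouse", values=df)
        with pytest.raises(KeyError, match="1C"):
            call_zga(table, MOUSE)

    def test_gate_mode_blocks_high_maternal(self):
        gated = SpeciesRuleset(
            species=MOUSE.species,
            stages=MOUSE.stages,
            conditions=MOUSE.conditions,
            maternal_stages=MOUSE.maternal_stages,
            maternal_mode="gate",
        )
        # ratios fire numerically but both maternal stages are >= 0.5 TPM
        table = make_table({"g1": [5, 5, 50, 50, 0.1, 0.1, 0.1, 0.1]})
        assert call_zga(table, gated).labels["g1"] != ZGA
        assert call_zga(table, MOUSE).labels["g1"] == ZGA  # floor mode: 50/5 = 10 > 3


class TestNonZga:
    def test_sum_below_cap(self):
        # 0.1 TPM in each of 7 embryo stages (MII excluded): sum 0.7 < 2
        table = make_table({"g1": [9.0] + [0.1] * 7})
        assert call_non_zga(table, MOUSE) == {"g1"}

    def test_single_high_stage_excluded(self):
        table = make_table({"g1": [0, 0, 0, 5, 0, 0, 0, 0]})
        assert call_non_zga(table, MOUSE) == set()

    def test_empty_table(self):
        table = make_table({})
        assert call_non_zga(table, MOUSE) == set()


class TestFoldChange:
    def test_simple_ratio(self):
        table = make_table({"g1": [0, 0, 4.0, 2.0, 0, 0, 0, 0]})
        fc = fold_change(table, "early2C", "late2C", pseudo=0)
        assert fc["g1"] == pytest.approx(2.0)

    def test_equal_zeros_give_unity(self):
        table = make_table({"g1": [0] * 8})
        assert fold_change(table, "late2C", "1C").loc["g1"] == pytest.approx(1.0)

    def test_matches_hand_computed_vector(self):
        vals = {"g%d" % i: [0, 0, a, b, 0, 0, 0, 0] for i, (a, b) in enumerate([(4, 2), (1, 1), (0, 3), (9, 0), (2.5, 5)])}
        table = make_table(vals)
        fc = fold_change(table, "early2C", "late2C", pseudo=0.01)
        expected = [(a + 0.01) / (b + 0.01) for a, b in [(4, 2), (1, 1), (0, 3), (9, 0), (2.5, 5)]]
        assert np.allclose(fc.to_numpy(), expected)


class TestMergeCandidates:
    def base_result(self):
        table = make_table({"g1": [0.1] * 8, "g2": [0.1, 0.1, 9, 9, 9, 9, 9, 9]})
        return call_zga(table, MOUSE)

    def test_adds_unassigned_gene(self):
        res = merge_candidates(self.base_result(), ["g9"])
        assert res.labels["g9"] == ZGA
        assert res.provenance["g9"] == "external_list"

    def test_existing_call_keeps_rules(self):
        res = merge_candidates(self.base_result(), ["g2"])
        assert res.labels["g2"] == ZGA
        assert "external_list" in res.provenance["g2"]
        assert res.fired_rules["g2"]

    def test_empty_external_is_identity(self):
        base = self.base_result()
        res = merge_candidates(base, [])
        assert res.labels == base.labels


def brute_force_call(table, ruleset):
    """Independent per-(gene, condition) evaluator."""
    out = {}
    for gene in table.values.index:
        row = table.values.loc[gene]
        fired = False
        for c in ruleset.conditions:
            den = max(row[c.denominator], ruleset.maternal_floor)
            if row[c.numerator] / den > c.threshold:
                fired = True
        if fired:
            out[gene] = ZGA
        elif sum(row[s] for s in table.stages if s != "MII") < ruleset.non_zga_sum_max:
            out[gene] = NON_ZGA
        else:
            out[gene] = UNASSIGNED
    return out


class TestProperties:
    def test_equivalence_with_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        for ruleset in (MOUSE, RULESETS["human"], RULESETS["bovine"]):
            for _ in range(170):  # ~500 tables over the three rulesets
                n = int(rng.integers(1, 8))
                vals = rng.exponential(2.0, size=(n, len(ruleset.stages)))
                vals[rng.random(vals.shape) < 0.3] = 0.0
                df = pd.DataFrame(vals, index=[f"g{i}" for i in range(n)], columns=list(ruleset.stages))
                table = StageExpressionTable(species=ruleset.species, values=df)
                assert call_zga(table, ruleset).labels == brute_force_call(table, ruleset)

    def test_raising_zga_stage_never_turns_zga_into_non_zga(self):
        # raising expression can at most un-fire a ratio whose denominator
        # is itself an activation stage (-> unassigned); it can never
        # produce a nonZGA call because stage sums only grow
        rng = np.random.default_rng(7)
        for _ in range(50):
            vals = rng.exponential(2.0, size=(1, 8))
            df = pd.DataFrame(vals, index=["g"], columns=list(MOUSE.stages))
            table = StageExpressionTable(species="mouse", values=df)
            if call_zga(table, MOUSE).labels["g"] != ZGA:
                continue
            stage = rng.choice(MOUSE.zga_stages)
            df2 = df.copy()
            df2.loc["g", stage] *= 1 + rng.random() * 10
            assert call_zga(StageExpressionTable(species="mouse", values=df2), MOUSE).labels["g"] != NON_ZGA

    def test_raising_pure_numerator_stage_preserves_call(self):
        # late2C never appears as a denominator in the mouse ruleset, so
        # raising it keeps every fired ratio fired
        rng = np.random.default_rng(8)
        for _ in range(50):
            vals = rng.exponential(2.0, size=(1, 8))
            df = pd.DataFrame(vals, index=["g"], columns=list(MOUSE.stages))
            if call_zga(StageExpressionTable(species="mouse", values=df), MOUSE).labels["g"] != ZGA:
                continue
            df2 = df.copy()
            df2.loc["g", "late2C"] *= 1 + rng.random() * 10
            assert call_zga(StageExpressionTable(species="mouse", values=df2), MOUSE).labels["g"] == ZGA

    def test_zga_and_non_zga_disjoint(self):
        rng = np.random.default_rng(3)
        vals = rng.exponential(1.0, size=(50, 8))
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(50)], columns=list(MOUSE.stages))
        table = StageExpressionTable(species="mouse", values=df)
        res = call_zga(table, MOUSE)
        assert not (res.zga_genes & res.non_zga_genes)


def test_ruleset_yaml_roundtrip(tmp_path):
    import yaml

    from zgakit.expression import load_ruleset

    cfg = {
        "species": "mouse",
        "stages": list(MOUSE.stages),
        "conditions": [
            {"numerator": c.numerator, "denominator": c.denominator, "threshold": c.threshold}
            for c in MOUSE.conditions
        ],
        "maternal_stages": list(MOUSE.maternal_stages),
    }
    path = tmp_path / "ruleset.yaml"
    path.write_text(yaml.safe_dump(cfg))
    rs = load_ruleset(path)
    assert rs.conditions == MOUSE.conditions
    assert rs.maternal_floor == 0.5
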