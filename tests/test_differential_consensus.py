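import numpy as np
import pytest

from markdyn.differential_consensus import (
    DiffRecord,
    GeneCallSet,
    apply_thresholds,
    dual_condition_genes,
    maintained_genes,
    proportion_enrichment_z,
    records_to_gene_set,
    replicate_consensus,
    simple_differential_test,
)
from markdyn.synthetic_data import generate_differential_frame, generate_gene_set


def rec(target, q, lfc, support=(), contrast="m1", gene=None):
    return DiffRecord(
        target_id=target, contrast=contrast, q_value=q, log2_fold_change=lfc,
        replicate_support=frozenset(support), gene_id=gene,
    )


class TestThresholds:
    @pytest.mark.parametrize(
        "q,lfc,kept",
        [
            (0.05, 0.585, True),   # both boundaries inclusive
            (0.01, 0.3, False),    # fold change too small
            (0.06, 2.0, False),    # q too large
            (0.04, -0.9, True),    # negative fold changes count by magnitude
        ],
    )
    def test_boundaries(self, q, lfc, kept):
        out = apply_thresholds([rec("r1", q, lfc)])
        assert (len(out) == 1) is kept

    def test_min_fold_must_exceed_one(self):
        with pytest.raises(ValueError):
            apply_thresholds([rec("r1", 0.01, 1.0)], min_fold=0.9)

    def test_commutes_with_replicate_consensus(self):
        records = [
            rec(f"r{i}", q, lfc, support)
            for i, (q, lfc, support) in enumerate(
                [
                    (0.01, 1.0, ("a", "b")),
                    (0.2, 1.0, ("a", "b", "c")),
                    (0.01, 0.1, ("a", "b")),
                    (0.01, 2.0, ("a",)),
                ]
            )
        ]
        ab = replicate_consensus(apply_thresholds(records))
        ba = apply_thresholds(replicate_consensus(records))
        assert ab == ba


class TestReplicateConsensus:
    def test_toy_fixture_supports(self):
        supports = [3, 2, 1, 2, 0]
        records = [
            rec(f"r{i}", 0.01, 1.0, tuple(f"rep{j}" for j in range(s)))
            for i, s in enumerate(supports)
        ]
        assert len(replicate_consensus(records)) == 3

    def test_min_support_exceeding_replicates_rejected(self):
        with pytest.raises(ValueError):
            replicate_consensus([], min_support=4, n_replicates=3)


class TestDualCondition:
    def _set(self, genes, contrast="m1", direction="down"):
        return GeneCallSet(contrast, direction, frozenset(genes))

    def test_intersection(self):
        out = dual_condition_genes(self._set("ABC"), self._set("BCD", contrast="m2"))
        assert out.genes == {"B", "C"}

    @pytest.mark.parametrize("g1,g2", [("", "ABC"), ("AB", "CD")])
    def test_empty_or_disjoint(self, g1, g2):
        out = dual_condition_genes(self._set(g1), self._set(g2, contrast="m2"))
        assert out.genes == frozenset()

    def test_direction_mismatch_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            dual_condition_genes(self._set("AB"), self._set("AB", direction="up"))


class TestMaintained:
    def test_membership_rules(self):
        out = maintained_genes({"a", "b", "c"}, {"b", "c", "d"}, {"c"})
        assert out.genes == {"b"}


class TestProportionZ:
    def test_equal_proportions_give_zero(self):
        z, _ = proportion_enrichment_z(5, 10, 10, 20)
        assert z == 0.0

    def test_pooled_closed_form(self):
        z, _ = proportion_enrichment_z(8, 10, 2, 10)
        assert z == pytest.approx(0.6 / np.sqrt(0.25 * 0.2), rel=1e-9)

    def test_p_monotone_decreasing_in_z(self):
        pairs = [proportion_enrichment_z(k, 50, 10, 50) for k in (15, 25, 35)]
        zs = [z for z, _ in pairs]
        ps = [p for _, p in pairs]
        assert zs == sorted(zs)
        assert ps == sorted(ps, reverse=True)

    def test_degenerate_pooled_proportion_rejected(self):
        with pytest.raises(ValueError):
            proportion_enrichment_z(0, 10, 0, 10)


class TestPlantedRecovery:
    def test_precision_and_recall_of_dual_mutant_set(self):
        genes, _ = generate_gene_set(400, 20_000, seed=11)
        true_down = {g.gene_id for g in genes[:80]}
        frame, _ = generate_differential_frame(genes, true_down, seed=5)
        call_sets = {}
        for c in ("mut1", "mut2"):
            records = [
                rec(
                    row.transcript_id,
                    getattr(row, f"q_value_{c}"),
                    getattr(row, f"log2fc_{c}"),
                    tuple(f"rep{j}" for j in range(getattr(row, f"support_{c}"))),
                    contrast=c,
                    gene=row.gene_id,
                )
                for row in frame.itertuples(index=False)
            ]
            surviving = replicate_consensus(apply_thresholds(records))
            call_sets[c] = records_to_gene_set(surviving, c, "down")
        final = dual_condition_genes(call_sets["mut1"], call_sets["mut2"])
        tp = len(final.genes & true_down)
        precision = tp / len(final.genes)
        recall = tp / len(true_down)
        assert precision >= 0.95
        assert recall >= 0.95


class TestSimpleDifferentialTest:
    def test_planted_shift_detected_with_bh_correction(self, rng):
        n_targets, n_reps = 60, 4
        base = rng.normal(10, 1, size=(n_targets, n_reps))
        shifted = base.copy()
        shifted[:10] *= 4.0  # strong planted increase in the first 10 targets
        ids = [f"t{i}" for i in range(n_targets)]
        records = simple_differential_test(base, shifted, ids, contrast="c")
        hits = {r.target_id for r in apply_thresholds(records)}
        assert {f"t{i}" for i in range(10)} <= hits
        assert len(hits - {f"t{i}" for i in range(10)}) <= 3
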