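"""Over-representation statistics, quadrant-conditioned enrichment, and
core-gene selection bookkeeping."""

import math

import numpy as np
import pandas as pd
import pytest

from quadromics.containers import DeTable, GeneSetCollection
from quadromics.enrichment import (
    EnrichmentRecord,
    enrich,
    gene_pathway_matrix,
    hypergeom_p,
    quadrant_enrichment,
    select_core_genes,
)
from quadromics.errors import ConfigurationError, ValidationError


def hypergeom_tail_oracle(k, K, n, N):
    """Exact tail P(X >= k) by direct summation of the hypergeometric pmf."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def make_de(log2fc: dict) -> DeTable:
    table = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": 0.001, "padj": 0.01, "status": "NS"}
    )
    table.index.name = "gene"
    return DeTable(table=table, layer="mrna", log2fc_cutoff=0.585, alpha=0.05)


class TestHypergeomP:
    def test_complete_overlap_small_universe(self):
        assert hypergeom_p(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_overlap_p_is_one(self):
        assert hypergeom_p(0, 5, 5, 10) == 1.0

    def test_matches_enumeration(self):
        assert hypergeom_p(8, 10, 10, 20) == pytest.approx(
            hypergeom_tail_oracle(8, 10, 10, 20), rel=1e-12
        )

    @pytest.mark.parametrize("k,K,n,N", [(6, 5, 5, 10), (1, 11, 5, 10), (1, 5, 11, 10)])
    def test_impossible_configuration_rejected(self, k, K, n, N):
        with pytest.raises(ValidationError):
            hypergeom_p(k, K, n, N)


class TestEnrich:
    def test_maximal_overlap_set_ranks_first(self):
        sets = GeneSetCollection(
            sets={
                "SetA": ("d", ("G1", "G2", "G3")),
                "SetB": ("d", ("G8", "G9")),
            }
        )
        background = [f"G{i}" for i in range(1, 11)]
        records = enrich(["G1", "G2", "G3"], background, sets)
        assert records[0].set_name == "SetA"
        assert records[0].k == 3

    def test_disjoint_query_all_p_one(self):
        sets = GeneSetCollection(sets={"SetA": ("d", ("G1", "G2"))})
        records = enrich(["G9", "G10"], [f"G{i}" for i in range(1, 11)], sets)
        assert all(r.p == 1.0 for r in records)

    def test_background_size_contract(self):
        sets = GeneSetCollection(sets={"SetA": ("d", ("G1",))})
        records = enrich(["G1"], [f"G{i}" for i in range(1, 8)], sets)
        assert records[0].N == 7

    def test_genes_outside_background_ignored(self):
        sets = GeneSetCollection(sets={"SetA": ("d", ("G1", "G2", "ZZZ"))})
        background = [f"G{i}" for i in range(1, 11)]
        a = enrich(["G1", "G2"], background, sets)
        b = enrich(["G1", "G2", "OUTSIDER"], background, sets)
        assert a[0].p == b[0].p
        assert a[0].K == 2  # ZZZ not in background

    def test_empty_background_rejected(self):
        sets = GeneSetCollection(sets={"SetA": ("d", ("G1",))})
        with pytest.raises(ConfigurationError):
            enrich(["G1"], [], sets)

    def test_significant_count_monotone_in_alpha(self, rng):
        genes = [f"G{i}" for i in range(60)]
        sets = GeneSetCollection(
            sets={
                f"S{j}": ("d", tuple(rng.choice(genes, size=10, replace=False)))
                for j in range(12)
            }
        )
        query = genes[:15]
        previous = 0
        for alpha in (0.01, 0.05, 0.2, 0.8):
            n_sig = sum(r.significant for r in enrich(query, genes, sets, alpha=alpha))
            assert n_sig >= previous
            previous = n_sig


def test_quadrant_enrichment_recovers_planted_set():
    spec = []
    for i in range(8):
        spec.append((f"Q8GENE{i}", 0.0, "NS", -1.0, "Down"))
    for i in range(40):
        spec.append((f"BG{i}", 0.0, "NS", 0.0, "NS"))
    pairs = pd.DataFrame(
        spec, columns=["gene", "mrna_log2fc", "mrna_status", "protein_log2fc", "protein_status"]
    ).set_index("gene")
    from quadromics.quadrants import classify_pairs

    pairs = classify_pairs(pairs)
    sets = GeneSetCollection(
        sets={
            "PLANTED": ("d", tuple(f"Q8GENE{i}" for i in range(8))),
            "RANDOM": ("d", tuple(f"BG{i}" for i in range(10))),
        }
    )
    results = quadrant_enrichment(pairs, sets)
    assert "Q5" not in results
    assert results["Q8"][0].set_name == "PLANTED"
    assert results["Q8"][0].significant


def test_empty_quadrant_is_empty_list_not_error():
    pairs = pd.DataFrame(
        [("A", 1.0, "Up", 1.0, "Up")],
        columns=["gene", "mrna_log2fc", "mrna_status", "protein_log2fc", "protein_status"],
    ).set_index("gene")
    from quadromics.quadrants import classify_pairs

    sets = GeneSetCollection(sets={"S": ("d", ("A",))})
    results = quadrant_enrichment(classify_pairs(pairs), sets)
    assert list(results) == ["Q3"]


def record(name, members, adj_p=0.01, **kw):
    members = tuple(members)
    return EnrichmentRecord(
        set_name=name, k=len(members), K=len(members), n=10, N=100,
        p=adj_p / 2, adj_p=adj_p, members=members, significant=adj_p < 0.05, **kw
    )


class TestCoreGenes:
    def test_hub_connectivity_counted_over_significant_sets(self):
        records = [
            record("S1", ["HUB", "A"]),
            record("S2", ["HUB", "B"]),
            record("S3", ["HUB", "C"]),
            record("NOTSIG", ["HUB", "D"], adj_p=0.5),
        ]
        de = make_de({g: 1.0 for g in "ABCD"} | {"HUB": -2.0})
        sel = select_core_genes(records, de, target_size=1)
        assert sel.hub_genes == ("HUB",)
        assert sel.connectivity["HUB"] == 3

    def test_no_supplementation_when_enough_hubs(self):
        records = [
            record("S1", [f"H{i}" for i in range(25)]),
            record("S2", [f"H{i}" for i in range(25)]),
        ]
        de = make_de({f"H{i}": 1.0 for i in range(25)})
        sel = select_core_genes(records, de, target_size=20)
        assert len(sel.hub_genes) == 25
        assert sel.supplemental_genes == ()

    def test_supplementation_by_hand_enumeration(self):
        """One hub (in all three sets); each set then contributes its top-3
        |log2FC| non-selected members."""
        records = [
            record("S1", ["HUB", "A1", "A2", "A3"], adj_p=0.001),
            record("S2", ["HUB", "B1", "B2", "B3"], adj_p=0.002),
            record("S3", ["HUB", "C1", "C2", "C3"], adj_p=0.003),
        ]
        fc = {"HUB": 0.5}
        for prefix in "ABC":
            for i in (1, 2, 3):
                fc[f"{prefix}{i}"] = float(i)
        sel = select_core_genes(records, make_de(fc), min_pathways=2, target_size=20, top_m=3)
        assert sel.hub_genes == ("HUB",)
        assert set(sel.supplemental_genes) == {
            "A1", "A2", "A3", "B1", "B2", "B3", "C1", "C2", "C3"
        }
        # within each set, supplementation order follows |log2FC| descending
        assert sel.supplemental_genes[:3] == ("A3", "A2", "A1")

    def test_no_significant_records_empty_selection(self):
        sel = select_core_genes([record("S", ["A"], adj_p=0.9)], make_de({"A": 1.0}))
        assert sel.selected == ()


class TestGenePathwayMatrix:
    def test_fully_dense_toy(self):
        records = [record("S1", ["A", "B"]), record("S2", ["A", "B"])]
        de = make_de({"A": 1.0, "B": -1.0})
        sel = select_core_genes(records, de, min_pathways=2, target_size=1)
        matrix, density, down = gene_pathway_matrix(sel, records, de)
        assert matrix.shape == (2, 2)
        assert density == 100.0
        assert down == 50.0

    def test_cells_hold_log2fc_where_member(self):
        records = [record("S1", ["A"]), record("S2", ["A", "B"])]
        de = make_de({"A": -1.92, "B": 0.7})
        sel = select_core_genes(records, de, min_pathways=1, target_size=1)
        matrix, _, _ = gene_pathway_matrix(sel, records, de)
        assert matrix.loc["A", "S1"] == -1.92
        assert np.isnan(matrix.loc["B", "S1"])
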