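import numpy as np
import pandas as pd
import pytest

from palgraph.expression import compute_cnr, compute_pal, normalize_median_of_ratios, seed_expression_score
from palgraph.interactome import InteractomeGraph, merge_pathways
from palgraph.pathway_builder import deduce_variants
from palgraph.pathway_db import Interaction, Pathway, PathwayCollection, PathwayNode
from palgraph.synthetic_data import SimulationConfig, generate_cohort, generate_pathway_collection


def make_pathway(name, nodes, edges, arr=None):
    """Compact pathway builder: nodes {id: members}, edges (src, tgt, type)."""
    return Pathway(
        name=name,
        nodes=[PathwayNode(nid, nid, frozenset(m)) for nid, m in nodes.items()],
        interactions=[Interaction(*e) for e in edges],
        arr=arr or {},
    )


@pytest.fixture
def toy_collection():
    """Two pathways sharing the {G1} node, one complex node, valid ARRs."""
    p1 = make_pathway(
        "alpha",
        {"a": {"G1"}, "b": {"G2"}, "c": {"FREM2", "X1", "X2"}},
        [("a", "b", "activation"), ("a", "c", "inhibition")],
        arr={"G1": 1.0, "G2": 1.0, "FREM2": -1.0, "X1": 0.5, "X2": 0.0},
    )
    p2 = make_pathway(
        "beta",
        {"n1": {"G1"}, "n2": {"G3"}, "n3": {"FREM2"}},
        [("n1", "n2", "activation"), ("n2", "n3", "binding/association")],
    )
    return PathwayCollection([p1, p2])


def simple_graph(edges, symmetric_types=("binding/association", "compound")):
    """Single-gene-node interactome from (src_gene, tgt_gene, itype) triples."""
    g = InteractomeGraph()
    for u, v, itype in edges:
        ku = g.add_node([u], u)
        kv = g.add_node([v], v)
        g.add_edge(ku, kv, itype, "test")
    return g


def random_interactome(rng, n_nodes=15, n_edges=30, types=None):
    from palgraph.pathway_db import INTERACTION_TYPES

    types = types or sorted(INTERACTION_TYPES)
    g = InteractomeGraph()
    keys = [g.add_node([f"N{i}"], f"N{i}") for i in range(n_nodes)]
    for _ in range(n_edges):
        u, v = rng.integers(n_nodes, size=2)
        if u == v:
            continue
        g.add_edge(keys[u], keys[v], types[rng.integers(len(types))], "rnd")
    return g


def biomarker_scores(cfg: SimulationConfig, seed: int):
    """Full scoring chain on one simulated cohort: (scores, clinical, truth)."""
    matrix, clinical, truth = generate_cohort(cfg, seed)
    collection, _ = generate_pathway_collection(cfg, seed)
    graph = merge_pathways(collection)
    variants = deduce_variants(graph, cfg.seed_gene)
    normalized = normalize_median_of_ratios(matrix)
    cnr = compute_cnr(normalized)
    scores = pd.DataFrame(index=pd.Index(cnr.samples, name="sample_id"))
    expr = seed_expression_score(normalized, cfg.seed_gene)
    scores[f"{cfg.seed_gene}_expr"] = expr.set_index("sample_id")["value"]
    for v in variants:
        scores[f"PAL{v.order}"] = compute_pal(cnr, v.to_pathway()).set_index("sample_id")["pal"]
    return scores, clinical, truth


@pytest.fixture(scope="session")
def strong_effect_cohort():
    """One cohort with a strong planted pathway shift (log2FC = 2)."""
    cfg = SimulationConfig(n_genes=300, n_lgg=100, n_gbm=100, log2fc=2.0)
    scores, clinical, truth = biomarker_scores(cfg, seed=11)
    return scores, clinical, truth


@pytest.fixture(scope="session")
def null_cohort():
    """One cohort with no pathway effect and no survival link."""
    cfg = SimulationConfig(n_genes=300, n_lgg=150, n_gbm=150, log2fc=0.0, beta=0.0)
    scores, clinical, truth = biomarker_scores(cfg, seed=12)
    return scores, clinical, truth


def rng_seeds(n, base=0):
    return [base + i for i in range(n)]


def assert_frames_close(a: pd.DataFrame, b: pd.DataFrame, **kw):
    pd.testing.assert_frame_equal(a, b, **kw)


@pytest.fixture
def counts_tsv(tmp_path):
    def _write(text, name="counts.tsv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def exp_matrix(values: dict, layer: str):
    """ExpressionMatrix from {gene: {sample: value}} mapping."""
    from palgraph.expression import ExpressionMatrix

    df = pd.DataFrame(values).T
    df.index.name = "gene"
    return ExpressionMatrix(values=df.astype(float), layer=layer)


@pytest.fixture(autouse=True)
def _seed_numpy_global():
    # legacy global state should never leak between tests
    np.random.seed(0)
    yield
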