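"""Synthetic pathway collections and glioma-like RNA-seq cohorts.

The generator emulates the statistical structure the analysis assumes, at
configurable scale:

* a pathway collection containing a seed-gene pathway with a known layered
  topology (a tree rooted at a complex node holding the seed gene), so the
  BFS layer sizes and the true activator/repressor roles are known by
  construction, plus decoy pathways that together cover all nine interaction
  types;
* negative-binomial counts with gene-specific baseline means; each sample
  carries a latent pathway activity (higher on average in GBM by a
  configurable log2 fold-change) that shifts pathway-gene means along the
  sign of their true ARR;
* exponential survival times whose log-hazard is proportional to the
  standardized latent activity (so Cox recovery is an honest test), with
  independent exponential censoring calibrated to a target censoring
  fraction;
* binary IDH / MGMT / 1p/19q covariates with grade-dependent frequencies and
  optional multi-sample patients (several profiles per patient with
  within-patient noise).

Default cohort sizes mirror the largest public glioma cohort analyzed in
this setting (505 LGG / 153 GBM); all randomness flows from one explicit
seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, write_counts
from .pathway_db import (
    Interaction,
    Pathway,
    PathwayCollection,
    PathwayNode,
    validate_collection,
    write_collection,
)

#: signed interaction types used for the seed pathway's tree edges
_SIGNED_TYPES = [
    ("activation", 1),
    ("inhibition", -1),
    ("phosphorylation", 1),
    ("repression", -1),
    ("dephosphorylation", -1),
    ("ubiquitination", -1),
]
_NEUTRAL_TYPES = ["binding/association", "compound", "dissociation"]
_ALL_TYPES = [t for t, _ in _SIGNED_TYPES] + _NEUTRAL_TYPES

GBM_SUBTYPES = ["mesenchymal", "classical", "proneural"]
LGM_SUBTYPES = [f"LGm{i}" for i in range(1, 7)]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study. Defaults are the baseline conditions.

    Expression: ``log2fc`` is the mean latent-activity difference between GBM
    and LGG (applied to pathway genes along sign(ARR)); ``activity_sd`` the
    within-grade spread of the latent activity (log2 units); ``dispersion``
    the NB dispersion (var = mu + dispersion * mu^2). Survival: hazards per
    day, ``beta`` the log-hazard per SD of latent activity, identical for OS
    and PFS; ``censoring`` the target censoring fraction.
    """

    n_genes: int = 20_000
    n_lgg: int = 505
    n_gbm: int = 153
    seed_gene: str = "FREM2"
    seed_node_size: int = 3
    layer_sizes: tuple[int, ...] = (3, 4, 5)
    genes_per_node: int = 2
    neutral_edges_per_layer: int = 1
    n_decoy_pathways: int = 3
    decoy_nodes: int = 6

    log2fc: float = 1.0
    activity_sd: float = 0.5
    dispersion: float = 0.2
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5

    os_base_hazard: float = 1.0 / 500.0
    pfs_base_hazard: float = 1.0 / 250.0
    beta: float = float(np.log(2))
    censoring: float = 0.5
    idh_log_hr: float = 0.0

    p_idh_mut: dict = field(default_factory=lambda: {"LGG": 0.8, "GBM": 0.1})
    p_codel_given_idh: dict = field(default_factory=lambda: {"LGG": 0.4, "GBM": 0.05})
    p_mgmt_meth: float = 0.45
    mean_age: dict = field(default_factory=lambda: {"LGG": 43.0, "GBM": 60.0})

    n_multisample_patients: int = 0
    samples_per_patient: int = 2
    within_patient_sd: float = 0.1

    def validate(self) -> None:
        if min(self.n_genes, self.n_lgg, self.n_gbm) <= 0:
            raise ValueError("counts must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for p in (self.censoring, self.p_mgmt_meth, *self.p_idh_mut.values(), *self.p_codel_given_idh.values()):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        n_pathway_genes = self.seed_node_size + self.genes_per_node * sum(self.layer_sizes)
        if n_pathway_genes + self.n_decoy_pathways * self.decoy_nodes > self.n_genes:
            raise ValueError("more pathway genes than n_genes")


# ---------------------------------------------------------------------------
# Pathway collection with planted ground truth
# ---------------------------------------------------------------------------


def generate_pathway_collection(cfg: SimulationConfig, seed: int):
    """Build a collection with a planted seed-gene pathway.

    Returns ``(collection, truth)`` where ``truth`` records the planted
    layers, per-order (n_nodes, n_edges, n_genes) triples and the true ARR of
    every pathway gene. The seed pathway is a tree rooted at a complex node
    containing the seed gene, so every gene has a unique directed path from
    the seed and its ARR is the product of edge signs along it (0 when the
    path uses a neutral-type edge). Decoy pathways use disjoint genes and,
    together with the seed pathway, cover all nine interaction types.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)

    seed_members = [cfg.seed_gene.upper()] + [f"{cfg.seed_gene.upper()}P{i}" for i in range(1, cfg.seed_node_size)]
    nodes = [PathwayNode("n0", "seed complex", frozenset(seed_members))]
    interactions: list[Interaction] = []
    truth_arr: dict[str, float] = {g: 1.0 for g in seed_members}
    layers: list[list[str]] = [["n0"]]
    node_sign = {"n0": 1}  # cumulative path sign; None for neutral-tainted
    gene_counter = 0
    per_order = {}
    node_counter = 1

    for depth, width in enumerate(cfg.layer_sizes, start=1):
        layer_ids = []
        parents = layers[depth - 1]
        for j in range(width):
            node_id = f"n{node_counter}"
            node_counter += 1
            members = []
            for _ in range(cfg.genes_per_node):
                members.append(f"PG{gene_counter:04d}")
                gene_counter += 1
            parent = parents[j % len(parents)]
            if j < cfg.neutral_edges_per_layer:
                itype, sign = _NEUTRAL_TYPES[depth % len(_NEUTRAL_TYPES)], 0
            else:
                itype, sign = _SIGNED_TYPES[int(rng.integers(len(_SIGNED_TYPES)))]
            interactions.append(Interaction(parent, node_id, itype))
            parent_sign = node_sign[parent]
            cum = 0 if (sign == 0 or parent_sign == 0) else parent_sign * sign
            node_sign[node_id] = cum
            for g in members:
                truth_arr[g] = float(cum)
            nodes.append(PathwayNode(node_id, f"layer{depth} node {j}", frozenset(members)))
            layer_ids.append(node_id)
        layers.append(layer_ids)
        n_nodes = sum(len(l) for l in layers[: depth + 1])
        genes = set(seed_members)
        for lid in [n for l in layers[1 : depth + 1] for n in l]:
            genes |= set(next(nd.members for nd in nodes if nd.node_id == lid))
        per_order[depth] = {"n_nodes": n_nodes, "n_edges": len(interactions), "n_genes": len(genes)}

    seed_pathway = Pathway(
        name=f"{cfg.seed_gene.upper()}_planted",
        nodes=nodes,
        interactions=interactions,
        arr=dict(truth_arr),
    )

    used_types = {e.itype for e in interactions}
    missing_types = [t for t in _ALL_TYPES if t not in used_types]
    decoys = []
    dg = 0
    for d in range(cfg.n_decoy_pathways):
        dnodes = []
        dedges = []
        for j in range(cfg.decoy_nodes):
            dnodes.append(PathwayNode(f"d{j}", f"decoy {d}.{j}", frozenset({f"DG{d}_{dg + j:04d}"})))
        dg += cfg.decoy_nodes
        for j in range(1, cfg.decoy_nodes):
            if missing_types:
                itype = missing_types.pop()
            else:
                itype = _ALL_TYPES[int(rng.integers(len(_ALL_TYPES)))]
            dedges.append(Interaction(f"d{j - 1}", f"d{j}", itype))
        decoys.append(Pathway(name=f"decoy_{d}", nodes=dnodes, interactions=dedges))

    collection = PathwayCollection([seed_pathway] + decoys)
    violations = validate_collection(collection)
    if violations:  # pragma: no cover - generator must emit valid collections
        raise AssertionError(f"generator produced an invalid collection: {violations}")
    truth = {
        "seed_gene": cfg.seed_gene.upper(),
        "seed_node_members": sorted(seed_members),
        "arr": {g: truth_arr[g] for g in sorted(truth_arr)},
        "per_order": per_order,
        "pathway_name": seed_pathway.name,
    }
    return collection, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """What was planted: per-sample latent activity and the generating model."""

    activity: pd.Series
    arr: dict[str, float]
    pathway_genes: list[str]
    per_order: dict
    beta: float
    log2fc: float
    censoring_target: float

    def to_json_dict(self) -> dict:
        return {
            "activity": {k: float(v) for k, v in self.activity.items()},
            "arr": self.arr,
            "pathway_genes": self.pathway_genes,
            "per_order": self.per_order,
            "beta": self.beta,
            "log2fc": self.log2fc,
            "censoring_target": self.censoring_target,
        }


def _censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving an expected censored fraction ~= target.

    For subject i with event hazard h_i and independent Exp(c) censoring,
    P(censored) = c / (c + h_i); solve mean_i P = target by bisection.
    """
    if target <= 0:
        return 0.0
    if target >= 1:
        raise ValueError("censoring fraction must be < 1")
    lo, hi = 1e-12, float(hazards.max()) * 1e6

    def frac(c: float) -> float:
        return float(np.mean(c / (c + hazards)))

    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def _survival(rng, hazards: np.ndarray, censoring: float):
    t_event = rng.exponential(1.0 / hazards)
    if censoring <= 0:
        return t_event, np.ones(len(hazards), dtype=int)
    c_rate = _censoring_rate(hazards, censoring)
    t_cens = rng.exponential(1.0 / c_rate, size=len(hazards))
    event = (t_event <= t_cens).astype(int)
    return np.minimum(t_event, t_cens), event


def generate_cohort(cfg: SimulationConfig, seed: int):
    """Simulate one cohort: (raw counts, clinical table, ground truth).

    Counts are negative binomial (gamma-Poisson) with lognormal baseline
    means; pathway-gene means in sample i are scaled by
    2**(activity_i * sign(ARR_g)) where activity_i ~ N(log2fc * 1[GBM],
    activity_sd). OS/PFS are exponential with log-hazard beta * standardized
    activity (plus an optional IDH term), censored independently at the
    configured fraction. Deterministic given (cfg, seed).
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    collection, truth = generate_pathway_collection(cfg, seed)
    pathway_genes = sorted(truth["arr"])
    arr = truth["arr"]

    n = cfg.n_lgg + cfg.n_gbm
    grades = np.array(["LGG"] * cfg.n_lgg + ["GBM"] * cfg.n_gbm)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    is_gbm = grades == "GBM"

    activity = rng.normal(np.where(is_gbm, cfg.log2fc, 0.0), cfg.activity_sd)

    # gene panel: pathway genes first, then decoy genes, then background
    decoy_genes = sorted(g for p in collection.pathways[1:] for g in p.gene_set())
    n_background = cfg.n_genes - len(pathway_genes) - len(decoy_genes)
    background = [f"BG{i:05d}" for i in range(n_background)]
    genes = pathway_genes + decoy_genes + background

    base_mean = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=len(genes)))
    signs = np.zeros(len(genes))
    for i, g in enumerate(pathway_genes):
        signs[i] = np.sign(arr[g])

    mu = base_mean[:, None] * np.power(2.0, signs[:, None] * activity[None, :])
    lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=mu * cfg.dispersion)
    counts = rng.poisson(lam).astype(int)

    # clinical covariates
    idh = np.where(
        rng.random(n) < np.vectorize(cfg.p_idh_mut.get)(grades).astype(float), "mut", "wt"
    )
    codel = np.where(
        (idh == "mut") & (rng.random(n) < np.vectorize(cfg.p_codel_given_idh.get)(grades).astype(float)),
        "codel",
        "non-codel",
    )
    codel = np.where(idh == "wt", "non-codel", codel)
    mgmt = np.where(rng.random(n) < cfg.p_mgmt_meth, "methylated", "unmethylated")
    age = np.clip(rng.normal(np.vectorize(cfg.mean_age.get)(grades).astype(float), 10.0), 18, 90)
    subtype = np.where(
        is_gbm,
        rng.choice(GBM_SUBTYPES, size=n),
        rng.choice(LGM_SUBTYPES, size=n),
    )

    z = (activity - activity.mean()) / activity.std()
    log_hr = cfg.beta * z + cfg.idh_log_hr * (idh == "mut")
    os_time, os_event = _survival(rng, cfg.os_base_hazard * np.exp(log_hr), cfg.censoring)
    pfs_time, pfs_event = _survival(rng, cfg.pfs_base_hazard * np.exp(log_hr), cfg.censoring)

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient_id": sample_ids,
            "grade": grades,
            "os_time": np.round(os_time, 1),
            "os_event": os_event,
            "pfs_time": np.round(pfs_time, 1),
            "pfs_event": pfs_event,
            "idh": idh,
            "codel_1p19q": codel,
            "mgmt": mgmt,
            "age": np.round(age, 1),
            "subtype": subtype,
        }
    )

    values = pd.DataFrame(counts, index=genes, columns=sample_ids)
    activity_s = pd.Series(activity, index=sample_ids, name="activity")

    if cfg.n_multisample_patients > 0:
        values, clinical, activity_s = _add_multisample_patients(
            rng, cfg, values, clinical, activity_s, base_mean, signs, genes
        )

    matrix = ExpressionMatrix(values=values, layer="raw")
    gt = GroundTruth(
        activity=activity_s,
        arr=arr,
        pathway_genes=pathway_genes,
        per_order=truth["per_order"],
        beta=cfg.beta,
        log2fc=cfg.log2fc,
        censoring_target=cfg.censoring,
    )
    return matrix, clinical, gt


def _add_multisample_patients(rng, cfg, values, clinical, activity_s, base_mean, signs, genes):
    """Append extra profiles for the first GBM patients (multi-region sampling)."""
    gbm_ids = clinical.loc[clinical["grade"] == "GBM", "sample_id"].tolist()
    chosen = gbm_ids[: cfg.n_multisample_patients]
    extra_cols, extra_rows, extra_act = {}, [], {}
    counter = 0
    for pid in chosen:
        base_act = activity_s[pid]
        row = clinical.loc[clinical["sample_id"] == pid].iloc[0].to_dict()
        for r in range(1, cfg.samples_per_patient):
            sid = f"{pid}R{r}"
            counter += 1
            act = base_act + rng.normal(0.0, cfg.within_patient_sd)
            mu = base_mean * np.power(2.0, signs * act)
            lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=mu * cfg.dispersion)
            extra_cols[sid] = rng.poisson(lam).astype(int)
            new_row = dict(row)
            new_row["sample_id"] = sid
            extra_rows.append(new_row)
            extra_act[sid] = act
    if extra_cols:
        values = pd.concat([values, pd.DataFrame(extra_cols, index=genes)], axis=1)
        clinical = pd.concat([clinical, pd.DataFrame(extra_rows)], ignore_index=True)
        activity_s = pd.concat([activity_s, pd.Series(extra_act)])
        activity_s.name = "activity"
    return values, clinical, activity_s


def generate_scale_graph(n_nodes: int, n_edges: int):
    """A connected single-gene interactome with exact node and edge counts.

    Deterministic circulant construction: edge i joins node i mod N to the
    node offset 1 + i // N ahead (all activation), so all (source, target)
    pairs are distinct for n_edges <= N(N-1) and offset-1 edges make the
    graph connected. Used to sanity-check whole-graph statistics at the
    scale of a real interactome without shipping one.
    """
    from .interactome import InteractomeGraph

    if n_edges > n_nodes * (n_nodes - 1):
        raise ValueError("too many edges for distinct ordered pairs")
    g = InteractomeGraph()
    keys = [g.add_node([f"G{i:05d}"], f"G{i:05d}") for i in range(n_nodes)]
    for i in range(n_edges):
        u = i % n_nodes
        v = (u + 1 + i // n_nodes) % n_nodes
        g.add_edge(keys[u], keys[v], "activation", "scale")
    if g.n_edges != n_edges:  # pragma: no cover - construction guarantees this
        raise AssertionError("edge collision in scale graph")
    return g


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------


def write_fixture_bundle(path: str | os.PathLike, cfg: SimulationConfig, seed: int) -> dict:
    """Write counts.tsv, clinical.tsv, pathways.json and truth.json under ``path``.

    Returns the file paths. Byte-identical across runs with the same
    (cfg, seed).
    """
    os.makedirs(path, exist_ok=True)
    matrix, clinical, gt = generate_cohort(cfg, seed)
    collection, _ = generate_pathway_collection(cfg, seed)
    files = {
        "counts": os.path.join(path, "counts.tsv"),
        "clinical": os.path.join(path, "clinical.tsv"),
        "pathways": os.path.join(path, "pathways.json"),
        "truth": os.path.join(path, "truth.json"),
        "config": os.path.join(path, "sim_config.json"),
    }
    write_counts(matrix, files["counts"])
    clinical.to_csv(files["clinical"], sep="\t", index=False)
    write_collection(collection, files["pathways"])
    with open(files["truth"], "w") as fh:
        json.dump(gt.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(files["config"], "w") as fh:
        cfg_dict = dataclasses.asdict(cfg)
        cfg_dict["layer_sizes"] = list(cfg.layer_sizes)
        json.dump({"seed": seed, "config": cfg_dict}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return files
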