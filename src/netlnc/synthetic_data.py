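"""Synthetic expression data with planted, recoverable structure.

A Gaussian latent-factor model produces every artifact the pipeline needs:

* *related* lncRNAs share a latent factor with the ICP genes so their
  pairwise Pearson correlation is ``rho_signal`` in expectation;
* each planted (lncRNA, pathway) pair makes the pathway's member genes load
  on that lncRNA's private factor, concentrating their purity-adjusted rank
  scores at the top of the list;
* *confounded* (lncRNA, gene) pairs correlate only through the tumor-purity
  latent variable, so their raw Pearson correlation is high
  (``confound_strength`` in expectation) while the purity-adjusted partial
  correlation is near zero;
* all remaining features are independent noise.

Everything is drawn from a single seeded generator in a fixed order, so two
calls with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_formats import (
    GENE,
    LNCRNA,
    EdgeList,
    ExpressionMatrix,
    GeneSetCollection,
    PurityVector,
)


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 120
    n_genes: int = 500          # non-ICP genes
    n_lncrnas: int = 300
    n_icp: int = 10
    n_pathways: int = 5
    pathway_size: int = 40
    rho_signal: float = 0.7     # lncRNA-ICP correlation for related lncRNAs
    rho_pathway: float = 0.7    # pathway-gene loading on the lncRNA private factor
    confound_strength: float = 0.6  # raw correlation induced purely by purity
    noise_sd: float = 1.0
    n_related: int = 20
    n_confounded: int = 20
    n_decoy_edges: int = 500
    ppi_degree: int = 5         # non-ICP partners per ICP gene in the PPI part
    missing_fraction: float = 0.0

    def validate(self) -> None:
        if self.n_pathways * self.pathway_size > self.n_genes:
            raise ConfigurationError("pathways need more genes than n_genes provides")
        if self.n_related > self.n_lncrnas:
            raise ConfigurationError("n_related exceeds n_lncrnas")
        if self.n_related + self.n_confounded > self.n_lncrnas:
            raise ConfigurationError("related + confounded lncRNAs exceed n_lncrnas")
        if self.n_confounded > self.n_genes - self.n_pathways * self.pathway_size:
            raise ConfigurationError("not enough free genes for confounded pairs")
        for name in ("rho_signal", "rho_pathway", "confound_strength"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ConfigurationError("missing_fraction must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """The planted parameters recovery is scored against."""

    icp_genes: list[str]
    related_lncrnas: list[str]
    planted_pairs: list[tuple[str, str]]
    purity_confounded_pairs: list[tuple[str, str]]
    lncrna_ids: list[str]
    pathway_names: list[str]
    generator_config: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["planted_pairs"] = [list(t) for t in self.planted_pairs]
        payload["purity_confounded_pairs"] = [list(t) for t in self.purity_confounded_pairs]
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        payload["planted_pairs"] = [tuple(t) for t in payload["planted_pairs"]]
        payload["purity_confounded_pairs"] = [
            tuple(t) for t in payload["purity_confounded_pairs"]
        ]
        return cls(**payload)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate(
    config: SimConfig | None = None, seed: int = 17
) -> tuple[ExpressionMatrix, PurityVector, EdgeList, GeneSetCollection, SyntheticTruth]:
    """Draw one synthetic dataset; deterministic given (config, seed)."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    m = cfg.n_samples

    samples = [f"S{i + 1:04d}" for i in range(m)]
    icp_ids = [f"ICP{i + 1:02d}" for i in range(cfg.n_icp)]
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    lnc_ids = [f"L{i + 1:04d}" for i in range(cfg.n_lncrnas)]

    purity_raw = np.clip(rng.beta(5.0, 2.0, size=m), 0.0, 1.0)
    z_purity = _standardize(purity_raw)

    icp_factor = rng.standard_normal(m)
    sd = cfg.noise_sd

    a = np.sqrt(cfg.rho_signal)
    b = np.sqrt(1.0 - cfg.rho_signal)
    icp_expr = a * icp_factor[None, :] + b * rng.standard_normal((cfg.n_icp, m))

    related = lnc_ids[: cfg.n_related]
    private = rng.standard_normal((cfg.n_related, m))
    lnc_expr = rng.standard_normal((cfg.n_lncrnas, m)) * sd
    lnc_expr[: cfg.n_related] = a * icp_factor[None, :] + b * private

    gene_expr = rng.standard_normal((cfg.n_genes, m)) * sd

    # planted pathway blocks: members load on the matching lncRNA's private factor
    pathway_names = [f"PATHWAY_{q + 1:02d}" for q in range(cfg.n_pathways)]
    pathway_members = {
        name: gene_ids[q * cfg.pathway_size : (q + 1) * cfg.pathway_size]
        for q, name in enumerate(pathway_names)
    }
    n_planted = min(cfg.n_pathways, cfg.n_related)
    planted_pairs = [(related[q], pathway_names[q]) for q in range(n_planted)]
    c = np.sqrt(cfg.rho_pathway)
    for q in range(n_planted):
        z_factor = _standardize(private[q])
        lo, hi = q * cfg.pathway_size, (q + 1) * cfg.pathway_size
        gene_expr[lo:hi] = (
            c * z_factor[None, :]
            + np.sqrt(1.0 - cfg.rho_pathway) * rng.standard_normal((cfg.pathway_size, m))
        )

    # confounded pairs: lncRNA and gene correlate only through purity
    conf_lncs = lnc_ids[cfg.n_lncrnas - cfg.n_confounded :]
    free_genes = gene_ids[cfg.n_pathways * cfg.pathway_size :]
    conf_genes = free_genes[len(free_genes) - cfg.n_confounded :]
    lam = np.sqrt(cfg.confound_strength)
    res = np.sqrt(1.0 - cfg.confound_strength)
    for i, (lnc, gene) in enumerate(zip(conf_lncs, conf_genes)):
        li = cfg.n_lncrnas - cfg.n_confounded + i
        gi = cfg.n_genes - cfg.n_confounded + i
        lnc_expr[li] = lam * z_purity + res * rng.standard_normal(m)
        gene_expr[gi] = lam * z_purity + res * rng.standard_normal(m)
    confounded_pairs = list(zip(conf_lncs, conf_genes))

    values = np.vstack([icp_expr, gene_expr, lnc_expr])
    feature_ids = icp_ids + gene_ids + lnc_ids
    if cfg.missing_fraction > 0.0:
        holes = rng.random(values.shape) < cfg.missing_fraction
        values = values.copy()
        values[holes] = np.nan
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=feature_ids, columns=samples),
        feature_class={f: (LNCRNA if f.startswith("L") else GENE) for f in feature_ids},
    )
    purity = PurityVector(values=pd.Series(purity_raw, index=samples))

    # interaction list: lncRNA-ICP candidates, confounded pairs, a small PPI,
    # and random decoy lncRNA-gene pairs
    rows_a: list[str] = []
    rows_b: list[str] = []
    for lnc in lnc_ids:
        for icp in icp_ids:
            rows_a.append(lnc)
            rows_b.append(icp)
    for lnc, gene in confounded_pairs:
        rows_a.append(lnc)
        rows_b.append(gene)
    for icp in icp_ids:
        partners = rng.choice(cfg.n_genes, size=cfg.ppi_degree, replace=False)
        for j in partners:
            rows_a.append(icp)
            rows_b.append(gene_ids[j])
    decoy_l = rng.integers(0, cfg.n_lncrnas, size=cfg.n_decoy_edges)
    decoy_g = rng.integers(0, cfg.n_genes, size=cfg.n_decoy_edges)
    for li, gi in zip(decoy_l, decoy_g):
        rows_a.append(lnc_ids[li])
        rows_b.append(gene_ids[gi])
    edges = EdgeList(edges=pd.DataFrame({"node_a": rows_a, "node_b": rows_b}))

    gene_sets = GeneSetCollection(
        sets={name: frozenset(members) for name, members in pathway_members.items()},
        descriptions={name: "synthetic pathway" for name in pathway_names},
    )
    truth = SyntheticTruth(
        icp_genes=icp_ids,
        related_lncrnas=list(related),
        planted_pairs=planted_pairs,
        purity_confounded_pairs=confounded_pairs,
        lncrna_ids=lnc_ids,
        pathway_names=pathway_names,
        generator_config=dataclasses.asdict(cfg),
        seed=seed,
    )
    return expr, purity, edges, gene_sets, truth


def simulate_graph(
    n_lncrnas: int = 500,
    n_icp: int = 10,
    seed: int = 17,
    min_degree: int = 1,
    max_degree: int = 3,
) -> nx.Graph:
    """A ready-made weighted co-expression graph (no expression sampling).

    Every lncRNA node attaches to between ``min_degree`` and ``max_degree``
    random ICP genes with weights in (0.2, 0.95); the ICP genes form a ring so
    the graph is connected.  Useful for exercising the propagation stage at a
    chosen node count.
    """
    rng = np.random.default_rng(seed)
    graph = nx.Graph()
    icp_ids = [f"ICP{i + 1:02d}" for i in range(n_icp)]
    for icp in icp_ids:
        graph.add_node(icp, cls=GENE, is_icp=True)
    for i in range(n_icp):
        j = (i + 1) % n_icp
        if icp_ids[i] != icp_ids[j]:
            graph.add_edge(icp_ids[i], icp_ids[j], weight=float(rng.uniform(0.2, 0.95)))
    for k in range(n_lncrnas):
        lnc = f"L{k + 1:04d}"
        graph.add_node(lnc, cls=LNCRNA, is_icp=False)
        degree = int(rng.integers(min_degree, max_degree + 1))
        for idx in rng.choice(n_icp, size=min(degree, n_icp), replace=False):
            graph.add_edge(lnc, icp_ids[idx], weight=float(rng.uniform(0.2, 0.95)))
    return graph


def shuffle_sample_labels(expr: ExpressionMatrix, seed: int = 0) -> ExpressionMatrix:
    """Permute each feature's values across samples independently.

    Destroys every cross-feature and feature-covariate correlation while
    keeping each feature's marginal distribution, giving a full null for
    calibration runs.
    """
    rng = np.random.default_rng(seed)
    values = expr.values.to_numpy(dtype=float).copy()
    for i in range(values.shape[0]):
        rng.shuffle(values[i])
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=expr.feature_ids, columns=expr.sample_ids),
        feature_class=dict(expr.feature_class),
    )


def recovery_report(
    truth: SyntheticTruth,
    top_lncrnas: list[str] | None = None,
    significant_pairs: list[tuple[str, str]] | None = None,
) -> dict[str, float]:
    """Precision/recall of planted structure in pipeline output.

    ``top_lncrnas`` is scored against the related lncRNAs,
    ``significant_pairs`` against the planted (lncRNA, pathway) pairs.
    Empty outputs yield precision NaN (flagged) and recall 0.
    """
    metrics: dict[str, float] = {}
    if top_lncrnas is not None:
        known = set(truth.lncrna_ids)
        unknown = [l for l in top_lncrnas if l not in known]
        if unknown:
            raise ConfigurationError(f"unknown lncRNA id(s) in output: {unknown[:5]}")
        planted = set(truth.related_lncrnas)
        tp = len(planted & set(top_lncrnas))
        metrics["lncrna_tp"] = float(tp)
        metrics["lncrna_recall"] = tp / len(planted) if planted else float("nan")
        metrics["lncrna_precision"] = tp / len(top_lncrnas) if top_lncrnas else float("nan")
    if significant_pairs is not None:
        known_pairs = {
            (l, p) for l in truth.lncrna_ids for p in truth.pathway_names
        }
        unknown_pairs = [pr for pr in significant_pairs if tuple(pr) not in known_pairs]
        if unknown_pairs:
            raise ConfigurationError(f"unknown (lncRNA, pathway) pair(s): {unknown_pairs[:5]}")
        planted = set(truth.planted_pairs)
        hits = planted & {tuple(p) for p in significant_pairs}
        metrics["pair_tp"] = float(len(hits))
        metrics["pair_recall"] = len(hits) / len(planted) if planted else float("nan")
        metrics["pair_precision"] = (
            len(hits) / len(significant_pairs) if significant_pairs else float("nan")
        )
    return metrics


def write_artifacts(
    out_dir: str | Path,
    expr: ExpressionMatrix,
    purity: PurityVector,
    edges: EdgeList,
    gene_sets: GeneSetCollection,
    truth: SyntheticTruth,
) -> None:
    """Write all five artifacts in the pipeline's standard plain-text formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr.values.to_csv(out / "expression.tsv", sep="\t", na_rep="NA",
                       index_label="feature_id", float_format="%.10g")
    with open(out / "classes.tsv", "w") as fh:
        fh.write("feature_id\tclass\n")
        for fid in expr.feature_ids:
            fh.write(f"{fid}\t{expr.feature_class[fid]}\n")
    with open(out / "purity.tsv", "w") as fh:
        fh.write("sample_id\tpurity\n")
        for sid, val in purity.values.items():
            fh.write(f"{sid}\t{val:.10g}\n")
    edges.edges[["node_a", "node_b"]].to_csv(out / "interactions.tsv", sep="\t", index=False)
    with open(out / "pathways.gmt", "w") as fh:
        for name, members in gene_sets:
            desc = gene_sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(members)) + "\n")
    with open(out / "icp_genes.txt", "w") as fh:
        for gid in truth.icp_genes:
            fh.write(gid + "\n")
    truth.to_json(out / "truth.json")
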