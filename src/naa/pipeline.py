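"""Config-driven orchestration of the full target-network workflow.

Stage order: DEP filter → pathway resolution → pairwise association
matrix → top pair → topology indicators → entropy weights → TOPSIS key
nodes → protected maximum-Ks-core → optional manual amendment → report.
The key nodes and the DEPs present in the top-pair associated network
form the protected set of the core decomposition.

Every stage logs its headline counts, all intermediate tables are
written to the output directory with fixed column orders and 6-decimal
coefficients, and identical config + inputs produce byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import assoc_net, coredecomp, graph_io, mcda, topology
from .assoc_net import AssociatedNetwork, AssociationCounts, AssociationScore, PairwiseResult
from .coredecomp import KCoreResult
from .graph_io import Interactome, ParseError, PathwayNetwork

__all__ = [
    "PipelineConfig",
    "TargetNetworkReport",
    "ConfigError",
    "validate_config",
    "resolve_pathway",
    "run_pipeline",
]

log = logging.getLogger(__name__)

CONFIG_DEFAULTS = {
    "p_max": 0.05,
    "min_abs_lfc": 0.0,
    "topsis_threshold": 0.6,
    "weighted": True,
    "derived_mode": "any",
    "seed": 0,
}

KNOWN_KEYS = {
    "quant", "gmt", "networks_dir", "interactome", "signal", "process",
    "amend", "out_dir", *CONFIG_DEFAULTS,
}


class ConfigError(ValueError):
    """Raised with an itemized list of configuration problems."""


@dataclass(frozen=True)
class PipelineConfig:
    signal: tuple[str, ...]
    process: tuple[str, ...]
    out_dir: Path
    quant: Path | None = None
    gmt: Path | None = None
    networks_dir: Path | None = None
    interactome: Path | None = None
    amend: Path | None = None
    p_max: float = 0.05
    min_abs_lfc: float = 0.0
    topsis_threshold: float = 0.6
    weighted: bool = True
    derived_mode: str = "any"
    seed: int = 0


@dataclass(frozen=True)
class TargetNetworkReport:
    """Everything the pipeline computed, recomputable from its inputs."""

    dep_ids: frozenset[str]
    matrix: pd.DataFrame
    top_pair: tuple[str, str]
    counts: AssociationCounts
    score: AssociationScore
    indicators: pd.DataFrame
    entropy: pd.Series
    weights: pd.Series
    topsis_scores: pd.Series
    key_nodes: tuple[str, ...]
    protected: frozenset[str]
    kcore: KCoreResult
    target_nodes: frozenset[str]
    target_edges: frozenset[tuple[str, str]]

    def to_dict(self) -> dict:
        sc = self.score
        return {
            "n_deps": len(self.dep_ids),
            "matrix": {
                sig: {proc: _r(self.matrix.loc[sig, proc]) for proc in self.matrix.columns}
                for sig in self.matrix.index
            },
            "top_pair": list(self.top_pair),
            "counts": {
                "n_a": self.counts.n_a, "n_b": self.counts.n_b,
                "n_ab": self.counts.n_ab, "e_ab": self.counts.e_ab,
                "n_r": self.counts.n_r, "e_r": self.counts.e_r, "e_d": self.counts.e_d,
            },
            "score": {
                "c_n": _r(sc.c_n), "c_e": _r(sc.c_e), "c": _r(sc.c),
                "edgeless": sc.edgeless,
                "c_nw": _r(sc.c_nw), "c_ew": _r(sc.c_ew), "c_w": _r(sc.c_w),
            },
            "entropy": {k: _r(v) for k, v in self.entropy.items()},
            "indicator_weights": {k: _r(v) for k, v in self.weights.items()},
            "key_nodes": list(self.key_nodes),
            "n_protected": len(self.protected),
            "ks": self.kcore.ks,
            "core_nodes": sorted(self.kcore.core_nodes),
            "core_edge_count": len(self.kcore.core_edges),
            "target_node_count": len(self.target_nodes),
            "target_edge_count": len(self.target_edges),
        }


def _r(x, nd: int = 10):
    return None if x is None else round(float(x), nd)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML (flat key-value) pipeline configuration.

    Fills defaults (p_max 0.05, min_abs_lfc 0, topsis_threshold 0.6,
    derived mode ``any``, weighted true) and raises :class:`ConfigError`
    listing every problem found: unknown keys, missing files, thresholds
    out of range, or no way to resolve pathway names into networks.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    problems: list[str] = []
    for key in sorted(set(raw) - KNOWN_KEYS):
        problems.append(f"unknown key {key!r}")

    base = path.parent

    def get_path(key: str, required: bool = False) -> Path | None:
        val = raw.get(key)
        if val is None:
            if required:
                problems.append(f"missing required key {key!r}")
            return None
        p = Path(val)
        if not p.is_absolute():
            p = base / p
        if key != "out_dir" and not p.exists():
            problems.append(f"{key}: file not found: {p}")
        return p

    def get_names(key: str) -> tuple[str, ...]:
        val = raw.get(key)
        if val is None:
            problems.append(f"missing required key {key!r}")
            return ()
        if isinstance(val, str):
            val = [v.strip() for v in val.split(",") if v.strip()]
        if not isinstance(val, list) or not val:
            problems.append(f"{key}: expected a non-empty list of pathway names")
            return ()
        return tuple(str(v) for v in val)

    quant = get_path("quant")
    gmt = get_path("gmt")
    networks_dir = get_path("networks_dir")
    interactome = get_path("interactome")
    amend = get_path("amend")
    out_dir = get_path("out_dir", required=True)
    signal = get_names("signal")
    process = get_names("process")

    if gmt is None and networks_dir is None:
        problems.append("need 'gmt' (with 'interactome') and/or 'networks_dir'")
    if gmt is not None and interactome is None and networks_dir is None:
        problems.append("'gmt' pathway resolution requires an 'interactome'")

    merged = {**CONFIG_DEFAULTS, **{k: raw[k] for k in CONFIG_DEFAULTS if k in raw}}
    if not (0 < merged["p_max"] <= 1):
        problems.append(f"p_max: must be in (0, 1], got {merged['p_max']}")
    if merged["min_abs_lfc"] < 0:
        problems.append(f"min_abs_lfc: must be >= 0, got {merged['min_abs_lfc']}")
    if not (0 <= merged["topsis_threshold"] <= 1):
        problems.append(
            f"topsis_threshold: must be in [0, 1], got {merged['topsis_threshold']}"
        )
    if merged["derived_mode"] not in ("any", "cross-only"):
        problems.append(f"derived_mode: must be 'any' or 'cross-only'")

    if problems:
        raise ConfigError(f"{path}: " + "; ".join(problems))
    assert out_dir is not None
    return PipelineConfig(
        signal=signal, process=process, out_dir=out_dir,
        quant=quant, gmt=gmt, networks_dir=networks_dir,
        interactome=interactome, amend=amend,
        p_max=float(merged["p_max"]), min_abs_lfc=float(merged["min_abs_lfc"]),
        topsis_threshold=float(merged["topsis_threshold"]),
        weighted=bool(merged["weighted"]), derived_mode=str(merged["derived_mode"]),
        seed=int(merged["seed"]),
    )


def resolve_pathway(
    name: str,
    gmt_sets: Mapping[str, frozenset[str]],
    networks_dir: Path | None,
    interactome: Interactome | None,
) -> PathwayNetwork:
    """Turn a pathway name into a network.

    A ``+``-joined name (e.g. ``"HIF-1+FOXO"``) is the union of its parts.
    Each part resolves to an edge list ``<part>.tsv``/``<part>.sif`` in
    ``networks_dir`` when present (a companion ``<part>.nodes.tsv`` listing
    isolated nodes is honored); otherwise to the reference interactome
    induced on the part's GMT gene set (membership lists carry no edges of
    their own, so interactions are borrowed from the interactome).
    """
    parts = [p for p in name.split("+") if p]
    nets = []
    for part in parts:
        net = None
        if networks_dir is not None:
            for suffix in (".tsv", ".sif"):
                cand = networks_dir / f"{part}{suffix}"
                if cand.exists():
                    net = graph_io.read_edge_list(cand, name=part)
                    nodes_file = networks_dir / f"{part}.nodes.tsv"
                    if nodes_file.exists():
                        net = PathwayNetwork(
                            part,
                            net.nodes | graph_io.read_node_table(nodes_file),
                            net.edges,
                        )
                    break
        if net is None and part in gmt_sets:
            if interactome is None:
                raise ValueError(
                    f"pathway {part!r} is GMT-only but no interactome was given"
                )
            genes = gmt_sets[part]
            net = PathwayNetwork(
                name=part, nodes=genes, edges=interactome.edges_within(genes)
            )
        if net is None:
            raise ValueError(f"cannot resolve pathway {part!r} from networks_dir or GMT")
        nets.append(net)
    if len(nets) == 1:
        return nets[0]
    return assoc_net.combine_pathways(nets, name)


def _apply_amendments(
    nodes: set[str], edges: set[tuple[str, str]], amend_path: Path
) -> None:
    """Apply a manual curation list: add/remove nodes and edges in place."""
    with open(amend_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            op = fields[0]
            if op in ("add_node", "remove_node") and len(fields) == 2:
                n = graph_io.normalize_symbol(fields[1])
                if op == "add_node":
                    nodes.add(n)
                else:
                    nodes.discard(n)
                    edges.difference_update({e for e in edges if n in e})
            elif op in ("add_edge", "remove_edge") and len(fields) == 3:
                e = graph_io.canonical_edge(
                    graph_io.normalize_symbol(fields[1]),
                    graph_io.normalize_symbol(fields[2]),
                )
                if op == "add_edge":
                    nodes.update(e)
                    edges.add(e)
                else:
                    edges.discard(e)
            else:
                raise ParseError(f"{amend_path}:{lineno}: bad amendment {line!r}")


def _write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.6f") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def run_pipeline(cfg: PipelineConfig) -> TargetNetworkReport:
    """Execute the whole workflow and write all artifacts to ``cfg.out_dir``.

    Outputs: ``deps.tsv``, ``matrix.tsv``, ``assoc_nodes.tsv``,
    ``assoc_edges.tsv``, ``indicators.tsv``, ``topsis.tsv``, ``core.tsv``
    and a structured ``report.json``.  Identical configuration and inputs
    yield byte-identical files.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: DEP filter -------------------------------------------------
    if cfg.quant is not None:
        quant = graph_io.read_quant_table(cfg.quant)
        dep_ids = graph_io.filter_deps(quant, cfg.p_max, cfg.min_abs_lfc)
    else:
        quant = None
        dep_ids = frozenset()
    if not dep_ids:
        log.warning("DEP filter produced an empty set")
    log.info("stage deps: %d differentially expressed proteins", len(dep_ids))
    dep_df = pd.DataFrame({"protein_id": sorted(dep_ids)})
    dep_df.to_csv(out / "deps.tsv", sep="\t", index=False)

    # --- stage 2: resolve pathways -------------------------------------------
    gmt_sets: dict[str, frozenset[str]] = {}
    if cfg.gmt is not None:
        gmt_sets = dict(graph_io.read_gmt(cfg.gmt))
    interactome = (
        Interactome.from_edges(
            graph_io.read_edge_list(cfg.interactome, name="interactome").edges,
            normalize=False,
        )
        if cfg.interactome is not None
        else None
    )
    try:
        signal_nets = [
            resolve_pathway(n, gmt_sets, cfg.networks_dir, interactome)
            for n in cfg.signal
        ]
        process_nets = [
            resolve_pathway(n, gmt_sets, cfg.networks_dir, interactome)
            for n in cfg.process
        ]
    except ValueError as exc:
        raise RuntimeError(f"stage resolve: {exc}") from exc
    log.info("stage resolve: %d signal, %d process pathways",
             len(signal_nets), len(process_nets))

    # --- stage 3: pairwise association matrix --------------------------------
    pw = assoc_net.pairwise_matrix(
        signal_nets, process_nets, interactome,
        weighted=cfg.weighted, derived_mode=cfg.derived_mode,
    )
    _write_tsv(pw.matrix, out / "matrix.tsv")
    sig_name, proc_name = pw.best_pair
    log.info("stage pairwise: top pair (%s, %s), coefficient %.6f",
             sig_name, proc_name, float(pw.matrix.loc[sig_name, proc_name]))

    # --- stage 4: top-pair associated network ---------------------------------
    net_a = next(n for n in signal_nets if n.name == sig_name)
    net_b = next(n for n in process_nets if n.name == proc_name)
    assoc = assoc_net.build_association(net_a, net_b, interactome, cfg.derived_mode)
    counts = assoc_net.count_components(assoc, net_a.n_nodes, net_b.n_nodes)
    if counts.n_r == 0:
        log.warning("top pair has no overlapping nodes")
    nodes_df = pd.DataFrame(
        {"node": sorted(assoc.node_labels),
         "label": [assoc.node_labels[n] for n in sorted(assoc.node_labels)]}
    )
    nodes_df.to_csv(out / "assoc_nodes.tsv", sep="\t", index=False)
    edges_sorted = sorted(assoc.edge_labels)
    edges_df = pd.DataFrame(
        {"node1": [e[0] for e in edges_sorted],
         "node2": [e[1] for e in edges_sorted],
         "label": [assoc.edge_labels[e] for e in edges_sorted]}
    )
    edges_df.to_csv(out / "assoc_edges.tsv", sep="\t", index=False)

    # --- stage 5: topology + entropy + TOPSIS ---------------------------------
    indicators = topology.node_indicators(assoc)
    _write_tsv(indicators, out / "indicators.tsv")
    ew = mcda.entropy_weights(indicators)
    tr = mcda.topsis(indicators, ew)
    key_nodes = tuple(mcda.select_key_nodes(tr, cfg.topsis_threshold))
    log.info("stage topsis: %d key nodes above %.2f", len(key_nodes), cfg.topsis_threshold)
    topsis_df = pd.DataFrame({
        "d_plus": tr.d_plus, "d_minus": tr.d_minus, "c_score": tr.scores,
        "key": [n in key_nodes for n in tr.scores.index],
    })
    _write_tsv(topsis_df, out / "topsis.tsv")

    # --- stage 6: weighted score of the top pair ------------------------------
    if cfg.weighted:
        score = pw.best_score
    else:
        score = assoc_net.association_coefficient(counts)

    # --- stage 7: protected maximum core --------------------------------------
    protected = frozenset(key_nodes) | (dep_ids & assoc.nodes)
    kc = coredecomp.max_ks_core(assoc, protected)
    log.info("stage kcore: Ks=%d, %d core nodes, %d protected retained",
             kc.ks, len(kc.core_nodes), len(kc.protected_retained))

    # --- stage 8: optional manual amendment -----------------------------------
    target_nodes = set(kc.core_nodes)
    target_edges = set(kc.core_edges)
    if cfg.amend is not None:
        _apply_amendments(target_nodes, target_edges, cfg.amend)
        log.info("stage amend: target network now %d nodes, %d edges",
                 len(target_nodes), len(target_edges))

    core_nodes_sorted = sorted(target_nodes)
    core_df = pd.DataFrame({
        "node": core_nodes_sorted,
        "in_core": [n in kc.core_nodes for n in core_nodes_sorted],
        "protected": [n in protected for n in core_nodes_sorted],
    })
    core_df.to_csv(out / "core.tsv", sep="\t", index=False)
    core_edges_sorted = sorted(target_edges)
    pd.DataFrame({
        "node1": [e[0] for e in core_edges_sorted],
        "node2": [e[1] for e in core_edges_sorted],
    }).to_csv(out / "core_edges.tsv", sep="\t", index=False)

    report = TargetNetworkReport(
        dep_ids=dep_ids, matrix=pw.matrix, top_pair=pw.best_pair,
        counts=counts, score=score, indicators=indicators,
        entropy=ew.entropy, weights=ew.weights, topsis_scores=tr.scores,
        key_nodes=key_nodes, protected=protected, kcore=kc,
        target_nodes=frozenset(target_nodes), target_edges=frozenset(target_edges),
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
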