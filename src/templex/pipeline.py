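"""End-to-end pipeline: state sequences -> rule layers -> network analyses.

The stages mirror the analysis workflow: discretize each subject's time
series, estimate local transfer entropy per state-transition combination,
test combinations against the reshuffled null, build the four rule layers
per subject, then characterize the cohort's multiplex structure
(density/weight, reciprocity, motifs, hubs, modularity) and compare the two
groups measure by measure.

A single master seed deterministically derives independent streams for each
stage and subject via numpy's ``SeedSequence`` spawning, so reruns with the
same configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .centrality import hub_table
from .discretize import discretize, zscore
from .modularity import group_average, hierarchical_split, module_connectivity
from .motifs import motif_significance
from .multiplex import MultiplexNetwork, density, total_weight
from .reciprocity import multiplex_reciprocity
from .stats import compare_measures
from .te import (
    RULE_NAMES,
    build_rule_layers,
    combination_significance,
    subject_contributions,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "subject_rule_network"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; recorded verbatim in every output."""

    manifest: str
    out_dir: str
    threshold: float = 1.0
    k: int = 1
    l: int = 1
    n_perm: int = 100
    n_rand: int = 100
    alpha: float = 0.05
    hub_percentile: float = 90.0
    modularity_layers: list[str] = field(default_factory=lambda: list(RULE_NAMES))
    input_kind: str = "auto"  # "states", "bold", or "auto" (detect per file)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 20:
            raise ValueError("n_perm must be >= 20")
        if self.n_rand < 20:
            raise ValueError("n_rand must be >= 20")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _load_states(path: Path, cfg: RunConfig) -> np.ndarray:
    mat, labels = tio.read_timeseries(path)
    kind = cfg.input_kind
    if kind == "auto":
        is_discrete = np.isin(mat, (-1.0, 0.0, 1.0)).all()
        kind = "states" if is_discrete else "bold"
    if kind == "states":
        return mat.astype(np.int8)
    return discretize(zscore(mat, labels), cfg.threshold, labels).states


def subject_rule_network(
    states: np.ndarray,
    node_labels: list[str] | None = None,
    rules: dict | None = None,
) -> MultiplexNetwork:
    """The four rule-layer adjacency matrices of one subject as a multiplex."""
    layers = build_rule_layers(subject_contributions(states), rules)
    return MultiplexNetwork(
        layers=[layers[r] for r in layers],
        layer_names=list(layers),
        node_labels=node_labels or [],
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage; returns the output directory.

    Outputs (all delimited text + JSON sidecars, each carrying the config
    hash and seed): per-subject rule-layer adjacencies, combination
    significance summary, per-subject network metrics, reciprocity table,
    motif table, hub table, modularity partition, and group comparisons.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": asdict(cfg), "config_hash": cfg.config_hash()}
    timings: dict[str, float] = {}

    manifest = tio.read_manifest(cfg.manifest)
    ss = np.random.SeedSequence(cfg.seed)
    seed_sig, seed_recip, seed_motif, seed_mod = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )

    # --- discretize / load -------------------------------------------------
    t = time.time()
    subjects: dict[str, np.ndarray] = {}
    groups: dict[str, int] = {}
    for row in manifest.itertuples():
        p = Path(row.path)
        if not p.exists():
            raise FileNotFoundError(f"subject {row.subject_id}: missing file {p}")
        subjects[row.subject_id] = _load_states(p, cfg)
        groups[row.subject_id] = int(row.group)
    n_roi = next(iter(subjects.values())).shape[0]
    node_labels = [f"ROI{i}" for i in range(n_roi)]
    timings["load_discretize"] = time.time() - t

    # --- combination significance (cohort-pooled) --------------------------
    t = time.time()
    sig = combination_significance(
        list(subjects.values()), n_perm=cfg.n_perm, alpha=cfg.alpha, seed=seed_sig
    )
    pd.DataFrame({
        "combination": [str(c) for c in sig.combinations],
        "observed": sig.observed, "p_raw": sig.p_raw,
        "p_bonferroni": sig.p_bonferroni, "p_maxt": sig.p_maxt,
        "mse": sig.mse, "significant": sig.significant,
    }).to_csv(out / "combination_significance.csv", index=False)
    timings["significance"] = time.time() - t

    # --- per-subject rule layers and basic metrics -------------------------
    t = time.time()
    nets: dict[str, MultiplexNetwork] = {}
    metric_rows = []
    for sid, states in subjects.items():
        net = subject_rule_network(states, node_labels)
        nets[sid] = net
        tio.write_multiplex(net, out / "layers", prefix=f"{sid}_", metadata=None)
        for name, w in zip(net.layer_names, net.layers):
            metric_rows.append({
                "subject_id": sid, "group": groups[sid], "layer": name,
                "density": density(w), "total_weight": total_weight(w),
            })
    metrics = pd.DataFrame(metric_rows)
    metrics.to_csv(out / "layer_metrics.csv", index=False)
    timings["rule_layers"] = time.time() - t

    # --- group-average networks --------------------------------------------
    by_group: dict[int, MultiplexNetwork] = {}
    for g in sorted(set(groups.values())):
        sids = [s for s in nets if groups[s] == g]
        avg_layers = [
            group_average([nets[s].layer(name) for s in sids])
            for name in RULE_NAMES
        ]
        by_group[g] = MultiplexNetwork(
            layers=avg_layers, layer_names=list(RULE_NAMES), node_labels=node_labels
        )
        tio.write_multiplex(by_group[g], out / "group_average", prefix=f"g{g}_")

    # --- reciprocity, motifs, hubs on group-average nets --------------------
    t = time.time()
    recip_rows = []
    for g, net in by_group.items():
        for r in multiplex_reciprocity(net, n_null=cfg.n_rand, seed=seed_recip):
            recip_rows.append({"group": g, **vars(r)})
    pd.DataFrame(recip_rows).to_csv(out / "reciprocity.csv", index=False)
    timings["reciprocity"] = time.time() - t

    t = time.time()
    motif_rows = []
    for g, net in by_group.items():
        for s in motif_significance(net, n_rand=cfg.n_rand, seed=seed_motif):
            motif_rows.append({
                "group": g, "motif_type": s.motif_type,
                "layers": "+".join(s.layers), "order": s.order,
                "intensity": s.intensity, "count": s.count, "z": s.z, "p": s.p,
            })
    pd.DataFrame(motif_rows).to_csv(out / "motifs.csv", index=False)
    timings["motifs"] = time.time() - t

    t = time.time()
    hub_frames = []
    for g, net in by_group.items():
        df = hub_table(net, percentile=cfg.hub_percentile)
        df.insert(0, "group", g)
        hub_frames.append(df)
    pd.concat(hub_frames).to_csv(out / "hubs.csv", index=False)
    timings["centrality"] = time.time() - t

    # --- modularity on group-average layers --------------------------------
    t = time.time()
    part_rows, q_rows = [], []
    partitions: dict[tuple[int, str], dict[int, str]] = {}
    for g, net in by_group.items():
        for name in cfg.modularity_layers:
            w = net.layer(name)
            if w.sum() <= 0:
                logger.warning("group %d layer %s empty; skipping modularity", g, name)
                continue
            res = hierarchical_split(
                w, n_rand=cfg.n_rand, seed=seed_mod, n_restarts=20, null_restarts=5
            )
            paths = res.module_paths()
            partitions[(g, name)] = paths
            q_rows.append({
                "group": g, "layer": name, "q": res.q,
                "null_q_mean": float(res.null_q.mean()),
                "significant": res.significant,
            })
            for node, mp in paths.items():
                part_rows.append({
                    "group": g, "layer": name,
                    "node": node_labels[node], "module": mp,
                })
    pd.DataFrame(q_rows).to_csv(out / "modularity_q.csv", index=False)
    pd.DataFrame(part_rows).to_csv(out / "modularity_partitions.csv", index=False)
    timings["modularity"] = time.time() - t

    # --- group statistics ---------------------------------------------------
    t = time.time()
    g_ids = sorted(set(groups.values()))
    comparisons = []
    conn_rows: list[dict] = []
    if len(g_ids) == 2:
        g1, g2 = g_ids
        for measure in ("total_weight", "density"):
            m1, m2 = {}, {}
            for lay in RULE_NAMES:
                in_layer = metrics.layer == lay
                m1[f"{measure}:{lay}"] = metrics.loc[
                    (metrics.group == g1) & in_layer, measure
                ].to_numpy()
                m2[f"{measure}:{lay}"] = metrics.loc[
                    (metrics.group == g2) & in_layer, measure
                ].to_numpy()
            comparisons.append(compare_measures(m1, m2, alpha=cfg.alpha))
        # within/between module connectivity per subject, on group-1 partition
        for (g, name), paths in partitions.items():
            if g != g1 or name not in RULE_NAMES:
                continue
            top = np.array([
                int(paths.get(i, "0").split(".")[0]) for i in range(n_roi)
            ])
            conn1, conn2 = {}, {}
            for sid, net in nets.items():
                conn = module_connectivity(net.layer(name), top)
                store = conn1 if groups[sid] == g1 else conn2
                for (ma, mb), v in conn.items():
                    store.setdefault(f"module_conn:{ma}->{mb}:{name}", []).append(v)
                    conn_rows.append({
                        "subject_id": sid, "group": groups[sid], "layer": name,
                        "module_from": ma, "module_to": mb,
                        "kind": "within" if ma == mb else "between",
                        "mean_weight": v,
                    })
            shared = {k for k in conn1 if k in conn2}
            if shared:
                comparisons.append(compare_measures(
                    {k: np.array(conn1[k]) for k in shared},
                    {k: np.array(conn2[k]) for k in shared},
                    alpha=cfg.alpha,
                ))
    if comparisons:
        pd.concat(comparisons).to_csv(out / "group_comparisons.csv", index=False)
    if len(g_ids) == 2 and conn_rows:
        pd.DataFrame(conn_rows).to_csv(out / "module_connectivity.csv", index=False)
    timings["group_stats"] = time.time() - t

    meta["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    meta["total_s"] = round(time.time() - t0, 3)
    meta["surviving_combinations"] = [list(c) for c in sig.surviving]
    (out / "run.json").write_text(json.dumps(meta, indent=2))
    logger.info("pipeline finished in %.1fs", meta["total_s"])
    return out
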