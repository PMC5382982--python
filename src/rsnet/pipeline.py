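"""End-to-end study replica: simulate -> preprocess -> connectome -> metrics -> stats -> NBS.

One :class:`RunConfig` drives every stage; a master seed deterministically
derives all stage seeds, every intermediate artifact is written to the
run directory, and a manifest records parameters, seeds and per-file
checksums so a re-run with the same config reproduces identical outputs.
Stages consume the previous stage's on-disk outputs, so each is
independently re-runnable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .graphs import SparsityGrid, pearson_matrix
from .metrics import NODAL_MEASURES, subject_profile
from .preprocess import preprocess_subject
from .stats import GroupDesign, mixed_anova_global, nbs, nodal_auc_ttests, summarize_node_involvement
from .synthetic import CohortSpec, EffectSpec, default_effect_blocks, generate_cohort

__all__ = [
    "PreprocessParams",
    "StatParams",
    "RunConfig",
    "validate_config",
    "run_pipeline",
]

log = logging.getLogger("rsnet")

GLOBAL_METRICS = (
    "mean_clustering",
    "char_path_length",
    "c_norm",
    "l_norm",
    "small_world",
    "global_efficiency",
    "modularity",
    "n_modules",
)


@dataclass(frozen=True)
class PreprocessParams:
    n_drop: int = 50
    f_low: float = 0.01
    f_high: float = 0.1
    filter_order: int = 2
    mask_target: int = 300
    motion_threshold: float = 2.5


@dataclass(frozen=True)
class StatParams:
    alpha: float = 0.05
    fdr_q: float = 0.05
    primary_t: float = 3.1
    n_perm: int = 10000
    tails: tuple[str, ...] = ("lesion<sham", "lesion>sham")


@dataclass
class RunConfig:
    """Full configuration of a pipeline run; defaults are the study-replica values."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    effect: EffectSpec | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    sparsity_min: float = 0.05
    sparsity_max: float = 0.50
    sparsity_step: float = 0.05
    n_rand: int = 100
    edge_rank: str = "signed"
    stats: StatParams = field(default_factory=StatParams)
    seed: int = 0
    outdir: str = "rsnet_run"

    def __post_init__(self) -> None:
        if self.effect is None:
            reduced, increased = default_effect_blocks(self.cohort)
            self.effect = EffectSpec(
                reduced_block=reduced,
                increased_block=increased,
                reduction_factor=0.5,
                increase_factor=1.3,
            )

    def grid(self) -> SparsityGrid:
        return SparsityGrid.from_range(self.sparsity_min, self.sparsity_max, self.sparsity_step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect"]["reduced_block"] = sorted(self.effect.reduced_block)
        d["effect"]["increased_block"] = sorted(self.effect.increased_block)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortSpec(**d["cohort"])
        if d.get("effect") is not None:
            eff = dict(d["effect"])
            eff["reduced_block"] = frozenset(eff.get("reduced_block", ()))
            eff["increased_block"] = frozenset(eff.get("increased_block", ()))
            d["effect"] = EffectSpec(**eff)
        if "preprocess" in d:
            d["preprocess"] = PreprocessParams(**d["preprocess"])
        if "stats" in d:
            st = dict(d["stats"])
            if "tails" in st:
                st["tails"] = tuple(st["tails"])
            d["stats"] = StatParams(**st)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        d["stats"]["tails"] = list(self.stats.tails)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def validate_config(cfg: RunConfig) -> list[str]:
    """Check every sub-spec invariant; returns human-readable violations."""
    violations: list[str] = []
    try:
        dataclasses.replace(cfg.cohort)
    except ValueError as e:
        violations.append(f"cohort: {e}")
    try:
        dataclasses.replace(cfg.effect)
        if cfg.effect.reduced_block and max(cfg.effect.reduced_block) >= cfg.cohort.n_nodes:
            violations.append("effect: reduced_block index out of range")
        if cfg.effect.increased_block and max(cfg.effect.increased_block) >= cfg.cohort.n_nodes:
            violations.append("effect: increased_block index out of range")
    except ValueError as e:
        violations.append(f"effect: {e}")
    p = cfg.preprocess
    nyquist = 0.5 / cfg.cohort.tr_seconds
    if not 0 <= p.n_drop < cfg.cohort.n_volumes:
        violations.append("preprocess.n_drop: must lie in [0, n_volumes)")
    if not 0 < p.f_low < p.f_high < nyquist:
        violations.append("preprocess band: need 0 < f_low < f_high < Nyquist")
    if p.mask_target < 2:
        violations.append("preprocess.mask_target: must be at least 2")
    if p.mask_target > cfg.cohort.n_volumes - p.n_drop:
        violations.append("preprocess.mask_target: exceeds available volumes after drop")
    try:
        cfg.grid()
    except ValueError as e:
        violations.append(f"sparsity grid: {e}")
    if cfg.n_rand < 1:
        violations.append("n_rand: must be at least 1")
    if cfg.edge_rank not in ("signed", "absolute"):
        violations.append("edge_rank: must be 'signed' or 'absolute'")
    s = cfg.stats
    if not 0 < s.alpha < 1:
        violations.append("stats.alpha: must lie in (0, 1)")
    if not 0 < s.fdr_q < 1:
        violations.append("stats.fdr_q: must lie in (0, 1)")
    if s.primary_t <= 0:
        violations.append("stats.primary_t: must be positive")
    if s.n_perm < 100:
        violations.append("stats.n_perm: must be at least 100")
    for t in s.tails:
        if t not in ("lesion<sham", "lesion>sham"):
            violations.append(f"stats.tails: unknown tail {t!r}")
    return violations


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stage_simulate(cfg: RunConfig) -> Path:
    out = Path(cfg.outdir) / "simulate"
    cohort = dataclasses.replace(cfg.cohort, seed=_stage_seed(cfg.seed, "simulate"))
    subjects = generate_cohort(cohort, cfg.effect)
    _io.write_cohort(out, subjects, seed=cohort.seed)
    log.info("simulate: wrote %d subjects to %s", len(subjects), out)
    return out


def stage_preprocess(cfg: RunConfig) -> Path:
    src = Path(cfg.outdir) / "simulate"
    out = Path(cfg.outdir) / "preprocess"
    subjects = _io.read_cohort(src)
    p = cfg.preprocess
    cleaned = []
    for s in subjects:
        try:
            ts = preprocess_subject(
                s.ts,
                s.nuisance,
                n_drop=p.n_drop,
                f_low=p.f_low,
                f_high=p.f_high,
                filter_order=p.filter_order,
                target=p.mask_target,
            )
        except ValueError as e:
            raise RuntimeError(f"preprocess failed for subject {s.ts.subject_id}: {e}") from e
        # keep the nuisance table row-aligned with the masked series
        kept = np.flatnonzero(s.ts.valid[p.n_drop :])[: p.mask_target]
        nuis = dataclasses.replace(
            s.nuisance, regressors=s.nuisance.regressors[p.n_drop :][kept]
        )
        cleaned.append(dataclasses.replace(s, ts=ts, nuisance=nuis))
    _io.write_cohort(out, cleaned, seed=None)
    log.info("preprocess: %d subjects -> %d volumes each", len(cleaned), p.mask_target)
    return out


def stage_connectome(cfg: RunConfig) -> Path:
    src = Path(cfg.outdir) / "preprocess"
    out = Path(cfg.outdir) / "connectome"
    out.mkdir(parents=True, exist_ok=True)
    subjects = _io.read_cohort(src)
    index = []
    for s in subjects:
        try:
            cm = pearson_matrix(s.ts)
        except ValueError as e:
            raise RuntimeError(f"connectome failed for subject {s.ts.subject_id}: {e}") from e
        path = out / f"{cm.subject_id}_corr.csv"
        _io.write_connectivity(path, cm)
        index.append({"subject_id": cm.subject_id, "group": cm.group, "matrix": path.name})
    (out / "matrices.json").write_text(json.dumps({"subjects": index}, indent=2))
    return out


def _read_matrices(cfg: RunConfig):
    src = Path(cfg.outdir) / "connectome"
    index = json.loads((src / "matrices.json").read_text())["subjects"]
    return [
        _io.read_connectivity(src / e["matrix"], subject_id=e["subject_id"], group=e["group"])
        for e in index
    ]


def stage_metrics(cfg: RunConfig) -> Path:
    out = Path(cfg.outdir) / "metrics"
    out.mkdir(parents=True, exist_ok=True)
    matrices = _read_matrices(cfg)
    grid = cfg.grid()
    seeds = np.random.SeedSequence(_stage_seed(cfg.seed, "metrics")).spawn(len(matrices))
    long_rows = []
    auc_rows = []
    for cm, ss in zip(matrices, seeds):
        prof = subject_profile(
            cm,
            grid,
            n_rand=cfg.n_rand,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            edge_rank=cfg.edge_rank,
        )
        gm = prof.global_metrics.reset_index().melt(
            id_vars="sparsity", var_name="metric", value_name="value"
        )
        gm.insert(0, "subject", cm.subject_id)
        gm.insert(1, "group", cm.group)
        gm.insert(4, "node", "global")
        long_rows.append(gm)
        nd = prof.nodal.melt(id_vars=["sparsity", "node"], var_name="metric", value_name="value")
        nd.insert(0, "subject", cm.subject_id)
        nd.insert(1, "group", cm.group)
        long_rows.append(nd[["subject", "group", "sparsity", "metric", "node", "value"]])
        auc = prof.nodal_auc.reset_index().melt(id_vars="node", var_name="measure", value_name="auc")
        auc.insert(0, "subject", cm.subject_id)
        auc.insert(1, "group", cm.group)
        auc_rows.append(auc)
    pd.concat(long_rows, ignore_index=True).to_csv(out / "metrics_long.csv", index=False, float_format="%.10g")
    pd.concat(auc_rows, ignore_index=True).to_csv(out / "nodal_auc.csv", index=False, float_format="%.10g")
    (out / "metrics_manifest.json").write_text(
        json.dumps({"n_rand": cfg.n_rand, "grid": list(grid.values), "seed_stage": _stage_seed(cfg.seed, "metrics")}, indent=2)
    )
    return out


def stage_stats(cfg: RunConfig) -> Path:
    src = Path(cfg.outdir) / "metrics"
    out = Path(cfg.outdir) / "stats"
    out.mkdir(parents=True, exist_ok=True)
    long_df = pd.read_csv(src / "metrics_long.csv")
    auc_df = pd.read_csv(src / "nodal_auc.csv")
    pairs = long_df[["subject", "group"]].drop_duplicates()
    design = GroupDesign(tuple(pairs["subject"]), tuple(pairs["group"]))
    anova_rows = []
    posthoc_rows = []
    glob = long_df[long_df["node"] == "global"]
    for metric in GLOBAL_METRICS:
        sub = glob[glob["metric"] == metric][["subject", "group", "sparsity", "value"]]
        res = mixed_anova_global(sub, alpha=cfg.stats.alpha)
        tab = res.table.copy()
        tab.insert(0, "metric", metric)
        anova_rows.append(tab)
        ph = res.posthoc.copy()
        ph.insert(0, "metric", metric)
        posthoc_rows.append(ph)
    pd.concat(anova_rows, ignore_index=True).to_csv(out / "anova.csv", index=False, float_format="%.10g")
    pd.concat(posthoc_rows, ignore_index=True).to_csv(out / "anova_posthoc.csv", index=False, float_format="%.10g")

    n_hemi = cfg.cohort.n_hemisphere
    nodal_rows = []
    for measure in NODAL_MEASURES:
        piv = auc_df[auc_df["measure"] == measure].pivot(index="subject", columns="node", values="auc")
        res = nodal_auc_ttests(piv, design, q=cfg.stats.fdr_q, alpha=cfg.stats.alpha)
        res.insert(0, "measure", measure)
        res["hemisphere"] = np.where(res["node"].astype(int) < n_hemi, "ipsi", "contra")
        nodal_rows.append(res)
    pd.concat(nodal_rows, ignore_index=True).to_csv(out / "nodal_tests.csv", index=False, float_format="%.10g")
    return out


def stage_nbs(cfg: RunConfig) -> Path:
    out = Path(cfg.outdir) / "nbs"
    out.mkdir(parents=True, exist_ok=True)
    matrices = _read_matrices(cfg)
    design = GroupDesign.from_subjects(matrices)
    seed = _stage_seed(cfg.seed, "nbs")
    edge_rows = []
    involvement = np.zeros(matrices[0].n_nodes, dtype=int)
    summary = {"primary_t": cfg.stats.primary_t, "n_perm": cfg.stats.n_perm, "seed": seed, "tails": {}}
    for tail in cfg.stats.tails:
        res = nbs(
            matrices,
            design,
            primary_t=cfg.stats.primary_t,
            n_perm=cfg.stats.n_perm,
            tail=tail,
            seed=seed,
        )
        for comp_id, comp in enumerate(res.components):
            iu = comp[:, 0] * res.n_nodes + comp[:, 1]
            t_lookup = {
                (int(a), int(b)): float(res.edge_t[_edge_index(res.n_nodes, int(a), int(b))])
                for a, b in comp
            }
            for a, b in comp:
                edge_rows.append(
                    {
                        "tail": tail,
                        "node_i": int(a) + 1,
                        "node_j": int(b) + 1,
                        "t": t_lookup[(int(a), int(b))],
                        "component_id": comp_id,
                        "extent": int(res.extents[comp_id]),
                        "p_fwer": float(res.p_fwer[comp_id]),
                    }
                )
        involvement += summarize_node_involvement(res, alpha=cfg.stats.alpha)
        summary["tails"][tail] = {
            "n_components": len(res.components),
            "extents": [int(e) for e in res.extents],
            "p_fwer": [float(p) for p in res.p_fwer],
            "n_significant": len(res.significant(cfg.stats.alpha)),
        }
    pd.DataFrame(
        edge_rows, columns=["tail", "node_i", "node_j", "t", "component_id", "extent", "p_fwer"]
    ).to_csv(out / "nbs_edges.csv", index=False, float_format="%.10g")
    pd.DataFrame(
        {"node": np.arange(1, involvement.size + 1), "abnormal_connections": involvement}
    ).to_csv(out / "node_involvement.csv", index=False)
    (out / "nbs_summary.json").write_text(json.dumps(summary, indent=2))
    return out


def _edge_index(n: int, i: int, j: int) -> int:
    """Index of (i, j), i < j, in the row-major upper-triangle ordering."""
    return i * n - i * (i + 1) // 2 + (j - i - 1)


STAGES = ("simulate", "preprocess", "connectome", "metrics", "stats", "nbs")
_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "connectome": stage_connectome,
    "metrics": stage_metrics,
    "stats": stage_stats,
    "nbs": stage_nbs,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage in order and write a manifest with checksums.

    Raises on the first stage error, naming the stage (and, where known,
    the offending subject). Re-running with the same config reproduces
    byte-identical artifacts; the manifest's ``checksums`` block is the
    reproducibility contract.
    """
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    timings = {}
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](cfg)
        except Exception as e:
            raise RuntimeError(f"stage '{stage}' failed: {e}") from e
        timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", stage, timings[stage])
    checksums = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config": cfg.to_dict(),
        "master_seed": cfg.seed,
        "stage_seeds": {s: _stage_seed(cfg.seed, s) for s in ("simulate", "metrics", "nbs")},
        "timings_seconds": timings,
        "checksums": checksums,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
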