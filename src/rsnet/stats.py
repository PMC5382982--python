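"""Group inference on connectome metrics.

Three layers of comparison between lesion and sham groups:

* global metrics: two-factor mixed ANOVA (group between subjects,
  sparsity within subjects) with per-sparsity Bonferroni post hoc tests;
* nodal AUCs: two-sample t-test per node with Benjamini-Hochberg FDR
  across nodes, reporting both uncorrected and FDR-significant sets with
  direction of change;
* individual connections: the network-based statistic (NBS) on
  unthresholded correlation matrices -- edge-wise t-tests, a primary
  threshold, connected components of suprathreshold edges, and
  permutation of group labels to control the family-wise error rate of
  component extent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .graphs import ConnectivityMatrix

__all__ = [
    "GroupDesign",
    "AnovaResult",
    "NbsResult",
    "mixed_anova_global",
    "nodal_auc_ttests",
    "nbs",
    "summarize_node_involvement",
]


@dataclass(frozen=True)
class GroupDesign:
    """Subject-to-group assignment for a two-group comparison."""

    subject_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.subject_ids) != len(self.labels):
            raise ValueError("one label per subject required")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")
        bad = set(self.labels) - {"lesion", "sham"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.n_lesion == 0 or self.n_sham == 0:
            raise ValueError("both groups must be non-empty")

    @classmethod
    def from_subjects(cls, subjects) -> "GroupDesign":
        """Build from objects exposing ``subject_id`` and ``group``."""
        ids, labels = [], []
        for s in subjects:
            ts = getattr(s, "ts", s)
            ids.append(ts.subject_id)
            labels.append(ts.group)
        return cls(tuple(ids), tuple(labels))

    @property
    def n_lesion(self) -> int:
        return sum(1 for g in self.labels if g == "lesion")

    @property
    def n_sham(self) -> int:
        return sum(1 for g in self.labels if g == "sham")

    @property
    def n_subjects(self) -> int:
        return len(self.labels)

    def lesion_mask(self) -> np.ndarray:
        return np.asarray([g == "lesion" for g in self.labels])


@dataclass
class AnovaResult:
    """Mixed-ANOVA table plus per-sparsity Bonferroni post hoc tests."""

    table: pd.DataFrame
    posthoc: pd.DataFrame


def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    t, _ = sstats.ttest_ind(x, y, equal_var=True)
    return float(t)


def mixed_anova_global(
    metric_table: pd.DataFrame,
    design: GroupDesign | None = None,
    alpha: float = 0.05,
) -> AnovaResult:
    """Two-factor mixed ANOVA on one global metric.

    ``metric_table`` is long-format with columns ``subject``, ``group``,
    ``sparsity`` and ``value`` (``group`` may be omitted when ``design``
    is given). Group is the between-subject factor and sparsity the
    within-subject (repeated) factor; no sphericity correction is
    applied. Post hoc: a pooled two-sample t-test at each sparsity with
    Bonferroni-adjusted significance threshold alpha / n_sparsities.
    """
    df = metric_table.copy()
    if "group" not in df.columns:
        if design is None:
            raise ValueError("need a 'group' column or an explicit design")
        lut = dict(zip(design.subject_ids, design.labels))
        df["group"] = df["subject"].map(lut)
    required = {"subject", "group", "sparsity", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"metric table must have columns {sorted(required)}")
    counts = df.groupby(["subject", "sparsity"]).size()
    if (counts != 1).any():
        raise ValueError("every subject needs exactly one value per sparsity")
    per_group = df.groupby("group")["subject"].nunique()
    if (per_group < 2).any() or len(per_group) != 2:
        raise ValueError("need at least 2 subjects in each of the two groups")
    n_cells = df.groupby("subject").size().nunique()
    if n_cells != 1:
        raise ValueError("missing cells: subjects cover different sparsity sets")

    sparsities = np.sort(df["sparsity"].unique())
    if sparsities.size == 1:
        # degenerate single-level within factor: one-way between ANOVA (F = t^2)
        piv = df.set_index("subject")
        les = piv.loc[piv["group"] == "lesion", "value"].to_numpy()
        sha = piv.loc[piv["group"] == "sham", "value"].to_numpy()
        f, p = sstats.f_oneway(les, sha)
        table = pd.DataFrame(
            [
                {
                    "Source": "group",
                    "F": float(f),
                    "ddof1": 1,
                    "ddof2": les.size + sha.size - 2,
                    "p_unc": float(p),
                }
            ]
        )
    else:
        import pingouin as pg

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.mixed_anova(
                data=df, dv="value", within="sparsity", subject="subject", between="group"
            )
        cols = [c for c in ("Source", "SS", "DF1", "DF2", "F", "p_unc", "np2") if c in aov.columns]
        table = aov[cols].rename(columns={"DF1": "ddof1", "DF2": "ddof2"})
        table["Source"] = table["Source"].replace({"Interaction": "interaction"})

    rows = []
    n_sp = sparsities.size
    for sp in sparsities:
        sub = df[df["sparsity"] == sp]
        les = sub.loc[sub["group"] == "lesion", "value"].to_numpy()
        sha = sub.loc[sub["group"] == "sham", "value"].to_numpy()
        t, p = sstats.ttest_ind(les, sha, equal_var=True)
        rows.append(
            {
                "sparsity": sp,
                "t": float(t),
                "p_uncorrected": float(p),
                "p_bonferroni": min(1.0, float(p) * n_sp),
                "significant": float(p) * n_sp < alpha,
            }
        )
    return AnovaResult(table=table, posthoc=pd.DataFrame(rows))


def nodal_auc_ttests(
    auc_table: pd.DataFrame,
    design: GroupDesign,
    q: float = 0.05,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-node two-sample t-tests on AUC values with BH-FDR across nodes.

    ``auc_table`` is subjects x nodes (index = subject id). Returns one
    row per node with t, uncorrected p, BH q-value, direction of the
    lesion-group change relative to sham ('I' increase / 'D' decrease),
    and the uncorrected-significant and FDR-significant flags.
    """
    missing = set(design.subject_ids) - set(auc_table.index)
    if missing:
        raise ValueError(f"AUC table missing subjects: {sorted(missing)}")
    x = auc_table.loc[list(design.subject_ids)].to_numpy(dtype=float)
    mask = design.lesion_mask()
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    les, sha = x[mask], x[~mask]
    both_const = (les.std(axis=0) == 0) & (sha.std(axis=0) == 0)
    if both_const.any():
        bad = [auc_table.columns[i] for i in np.flatnonzero(both_const)]
        raise ValueError(f"zero-variance nodes in both groups: {bad}")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sstats.ttest_ind(les, sha, axis=0, equal_var=equal_var)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    _, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    direction = np.where(les.mean(axis=0) >= sha.mean(axis=0), "I", "D")
    return pd.DataFrame(
        {
            "node": auc_table.columns.to_numpy(),
            "t": t,
            "p_uncorrected": p,
            "q_value": qvals,
            "direction": direction,
            "sig_uncorrected": p < alpha,
            "sig_fdr": qvals < q,
        }
    )


@dataclass
class NbsResult:
    """Suprathreshold components of the edge-wise contrast with FWER p-values."""

    n_nodes: int
    primary_t: float
    tail: str
    n_perm: int
    components: list[np.ndarray] = field(default_factory=list)  # each (k, 2) node pairs
    extents: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    p_fwer: np.ndarray = field(default_factory=lambda: np.empty(0))
    edge_t: np.ndarray | None = None
    null_max_extent: np.ndarray | None = None

    def significant(self, alpha: float = 0.05) -> list[int]:
        """Indices of components with p_fwer below alpha."""
        return [i for i, p in enumerate(self.p_fwer) if p < alpha]


def _upper_triangle_stack(matrices: list[ConnectivityMatrix]) -> tuple[np.ndarray, int]:
    n = matrices[0].n_nodes
    iu = np.triu_indices(n, 1)
    rows = []
    for m in matrices:
        if m.n_nodes != n:
            raise ValueError("all matrices must share the node set")
        rows.append(m.r[iu])
    return np.asarray(rows), n


def _batch_pooled_t(x: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Pooled two-sample t for each row-mask in ``masks`` (B x n) over x (n x E)."""
    n = x.shape[0]
    n1 = masks.sum(axis=1)
    n2 = n - n1
    tot = x.sum(axis=0)
    tot_sq = (x**2).sum(axis=0)
    s1 = masks @ x
    q1 = masks @ (x**2)
    m1 = s1 / n1[:, None]
    m2 = (tot[None, :] - s1) / n2[:, None]
    ss1 = q1 - n1[:, None] * m1**2
    ss2 = (tot_sq[None, :] - q1) - n2[:, None] * m2**2
    pooled = (ss1 + ss2) / (n - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2)[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / se
    return np.where(np.isfinite(t), t, 0.0)


class _UnionFind:
    __slots__ = ("parent", "size")

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}
        self.size: dict[int, int] = {}

    def find(self, a: int) -> int:
        parent = self.parent
        root = a
        while parent.setdefault(root, root) != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _components_from_edges(edge_pairs: np.ndarray) -> list[np.ndarray]:
    """Group an (m, 2) edge list into connected components of edges."""
    uf = _UnionFind()
    for a, b in edge_pairs:
        uf.union(int(a), int(b))
    groups: dict[int, list[int]] = {}
    for idx, (a, _b) in enumerate(edge_pairs):
        groups.setdefault(uf.find(int(a)), []).append(idx)
    comps = [edge_pairs[np.asarray(idx)] for idx in groups.values()]
    comps.sort(key=lambda c: (-len(c), c[0, 0], c[0, 1]))
    return comps


def _max_component_extent(edge_pairs: np.ndarray) -> int:
    if edge_pairs.shape[0] == 0:
        return 0
    uf = _UnionFind()
    for a, b in edge_pairs:
        uf.union(int(a), int(b))
    counts: dict[int, int] = {}
    for a, _b in edge_pairs:
        r = uf.find(int(a))
        counts[r] = counts.get(r, 0) + 1
    return max(counts.values())


def nbs(
    matrices: list[ConnectivityMatrix],
    design: GroupDesign,
    primary_t: float = 3.1,
    n_perm: int = 10000,
    tail: str = "lesion<sham",
    seed: int | None = None,
    fisher_z: bool = False,
    batch: int = 200,
) -> NbsResult:
    """Network-based statistic on unthresholded correlation matrices.

    Each of the R(R-1)/2 connections gets a pooled two-sample t-statistic
    (lesion minus sham). Edges beyond ``primary_t`` in the requested tail
    form a suprathreshold graph whose connected components are the
    candidate effects; their extent (edge count) is compared against the
    null distribution of the maximal extent under ``n_perm`` random
    relabelings of subjects. Component p-values use the add-one
    permutation estimator (b + 1) / (n_perm + 1).
    """
    if primary_t <= 0:
        raise ValueError("primary_t must be positive")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if tail not in ("lesion<sham", "lesion>sham"):
        raise ValueError("tail must be 'lesion<sham' or 'lesion>sham'")
    if len(matrices) != design.n_subjects:
        raise ValueError("one matrix per design subject required")
    if design.n_lesion < 2 or design.n_sham < 2:
        raise ValueError("need at least 2 subjects per group")
    x, n_nodes = _upper_triangle_stack(matrices)
    if fisher_z:
        x = np.arctanh(np.clip(x, -1 + 1e-12, 1 - 1e-12))
    n_distinct = math.comb(design.n_subjects, design.n_lesion)
    if n_distinct < n_perm:
        warnings.warn(
            f"only {n_distinct} distinct relabelings exist for n_perm={n_perm}; "
            "permutation p-values are coarse",
            stacklevel=2,
        )
    mask = design.lesion_mask()
    sign = -1.0 if tail == "lesion<sham" else 1.0
    iu = np.triu_indices(n_nodes, 1)
    pairs = np.column_stack(iu)

    t_obs = _batch_pooled_t(x, mask[None, :].astype(float))[0]
    supra = sign * t_obs >= primary_t
    components = _components_from_edges(pairs[supra])
    extents = np.asarray([len(c) for c in components], dtype=int)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    n_subj = design.n_subjects
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm_masks = np.zeros((b, n_subj))
        for i in range(b):
            perm_masks[i, rng.permutation(n_subj)[: design.n_lesion]] = 1.0
        t_perm = _batch_pooled_t(x, perm_masks)
        hits = sign * t_perm >= primary_t
        for i in range(b):
            null_max[done + i] = _max_component_extent(pairs[hits[i]])
        done += b
    p_fwer = np.asarray(
        [(1 + int((null_max >= ext).sum())) / (n_perm + 1) for ext in extents]
    )
    return NbsResult(
        n_nodes=n_nodes,
        primary_t=primary_t,
        tail=tail,
        n_perm=n_perm,
        components=components,
        extents=extents,
        p_fwer=p_fwer,
        edge_t=t_obs,
        null_max_extent=null_max,
    )


def summarize_node_involvement(res: NbsResult, alpha: float = 0.05) -> np.ndarray:
    """Per-node count of abnormal connections in significant components.

    Sums, over components with p_fwer < alpha, the edges incident to
    each node; the total over nodes is twice the number of significant
    edges.
    """
    counts = np.zeros(res.n_nodes, dtype=int)
    for i in res.significant(alpha):
        for a, b in res.components[i]:
            counts[int(a)] += 1
            counts[int(b)] += 1
    return counts
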