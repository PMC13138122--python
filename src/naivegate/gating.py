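"""Hierarchical cluster-selection gating and Gaussian-density thresholds.

The gating procedure mirrors expert manual gating but replaces polygon gates
with cluster selection: each step re-clusters only the events its parent
step kept, using a step-specific marker set, and keeps or drops whole
clusters by rules on cluster-median expression ("high CD3", "low Fas", ...).
The debris/doublet/dead step runs twice to catch residual contamination.

Where cluster boundaries are too coarse — separating naive (CD45RA+ Fas−)
from memory CD4+ T cells across a continuum of intermediate intensities —
scalar thresholds are constructed per sample from the marker's density:

* CD45RA: the kernel density estimate is fitted with a sum of two Gaussian
  peaks and the threshold is the intersection of the two components between
  their means (the valley separating the negative and positive modes).
* Fas: the density of the CD45RA-positive subset is fitted with a single
  Gaussian and the threshold is μ + σ.

Naive subsets are then assigned by strict sequential precedence on manual
per-panel thresholds: CXCR3hi first, then CD38++, then CD25lo (CD4 only);
whatever remains is mature naive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .events import EventMatrix
from .graph import ClusterProfile, cluster_events, cluster_marker_profile
from .preprocess import scale_center

__all__ = [
    "MarkerRule",
    "GatingStep",
    "ThresholdGateStep",
    "DensityFit",
    "ThresholdSet",
    "ThresholdFailure",
    "select_clusters",
    "gaussian_intersect",
    "fit_two_gaussian_intersect",
    "fit_gaussian_mu_sigma",
    "gate_naive_cd4",
    "assign_naive_subsets",
    "propose_cd38_threshold_from_ccr9",
    "default_gating_tree",
    "default_subset_thresholds",
    "run_gating_tree",
    "GatingResult",
]


class ThresholdFailure(RuntimeError):
    """Density-threshold construction failed; donor flagged for manual gating."""


# ---------------------------------------------------------------------------
# Cluster-selection rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerRule:
    """A high/low rule on cluster-median expression of one marker.

    ``cluster_median_quantile`` mode compares each cluster's median with the
    given quantile of all cluster medians for that marker (parameter in
    [0, 1], default 0.5); ``fixed_threshold`` mode compares with an absolute
    asinh-scale value.
    """

    marker: str
    direction: str  # "high" | "low"
    mode: str = "cluster_median_quantile"
    parameter: float = 0.5

    def __post_init__(self) -> None:
        if self.direction not in ("high", "low"):
            raise ValueError("direction must be 'high' or 'low'")
        if self.mode not in ("cluster_median_quantile", "fixed_threshold"):
            raise ValueError(f"unknown rule mode {self.mode!r}")
        if self.mode == "cluster_median_quantile" and not 0 <= self.parameter <= 1:
            raise ValueError("quantile parameter must lie in [0, 1]")

    def passes(self, medians: np.ndarray) -> np.ndarray:
        """Boolean pass-vector over clusters given their medians for this marker."""
        if self.mode == "cluster_median_quantile":
            cut = np.quantile(medians, self.parameter)
        else:
            cut = self.parameter
        return medians > cut if self.direction == "high" else medians < cut


RuleGroup = Sequence[MarkerRule]


def _as_groups(rules) -> list[list[MarkerRule]]:
    groups = []
    for r in rules or []:
        groups.append([r] if isinstance(r, MarkerRule) else list(r))
    return groups


def select_clusters(
    profile: ClusterProfile,
    include_rules: Sequence[MarkerRule] = (),
    exclude_rules: Sequence[MarkerRule | RuleGroup] = (),
) -> list[int]:
    """Cluster ids passing every include rule and matching no exclude group.

    Include rules are conjunctive. Each exclude entry is either one rule or
    a conjunctive group (e.g. Treg = high CD25 AND low CD127); a cluster is
    dropped if any group matches fully.
    """
    clusters = np.asarray(profile.medians.index)
    keep = np.ones(len(clusters), dtype=bool)
    for rule in include_rules or []:
        keep &= rule.passes(profile.medians[rule.marker].to_numpy())
    for group in _as_groups(exclude_rules):
        hit = np.ones(len(clusters), dtype=bool)
        for rule in group:
            hit &= rule.passes(profile.medians[rule.marker].to_numpy())
        keep &= ~hit
    return [int(c) for c in clusters[keep]]


# ---------------------------------------------------------------------------
# Density thresholds
# ---------------------------------------------------------------------------

@dataclass
class DensityFit:
    """Gaussian peak fit to a kernel density curve.

    Each component is (A, μ, σ) with curve ``A · exp(−(x−μ)² / (2σ²))``;
    for two components, μ1 < μ2 after canonical ordering.
    """

    components: list[tuple[float, float, float]]
    grid: np.ndarray
    density: np.ndarray
    residual: float

    def __post_init__(self) -> None:
        if any(s <= 0 for _, _, s in self.components):
            raise ValueError("σ must be positive for every component")
        if len(self.components) == 2 and self.components[0][1] >= self.components[1][1]:
            raise ValueError("components must be ordered μ1 < μ2")


@dataclass
class ThresholdSet:
    """Per-marker scalar thresholds with provenance."""

    thresholds: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def set(self, marker: str, value: float, provenance: str) -> None:
        if not np.isfinite(value):
            raise ValueError(f"threshold for {marker} must be finite")
        self.thresholds[marker] = float(value)
        self.provenance[marker] = provenance

    def __getitem__(self, marker: str) -> float:
        return self.thresholds[marker]

    def __contains__(self, marker: str) -> bool:
        return marker in self.thresholds


def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def gaussian_intersect(
    a1: float, mu1: float, s1: float, a2: float, mu2: float, s2: float
) -> float:
    """Intersection of two Gaussian curves strictly between their means.

    Solves ``A1·exp(−(x−μ1)²/2σ1²) = A2·exp(−(x−μ2)²/2σ2²)`` in closed form
    (log difference is quadratic in x) and returns the root in (μ1, μ2).
    """
    if mu1 >= mu2:
        raise ValueError("requires mu1 < mu2")
    # log f1 - log f2 = c + b x + a x^2 = 0
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = mu1 / s1**2 - mu2 / s2**2
    c = (np.log(a1) - np.log(a2)) - mu1**2 / (2 * s1**2) + mu2**2 / (2 * s2**2)
    if abs(a) < 1e-300:
        roots = np.array([-c / b]) if b != 0 else np.array([])
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            roots = np.array([])
        else:
            sq = np.sqrt(disc)
            roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    inside = roots[(roots > mu1) & (roots < mu2)]
    if inside.size == 0:
        raise ThresholdFailure(
            f"no Gaussian intersection in ({mu1:.3g}, {mu2:.3g})"
        )
    return float(inside[0]) if inside.size == 1 else float(np.min(inside))


def _kde_curve(values: np.ndarray, grid_size: int = 512):
    kde = stats.gaussian_kde(values, bw_method="silverman")
    h = kde.factor * values.std(ddof=1)
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, grid_size)
    return grid, kde(grid)


def fit_two_gaussian_intersect(
    values: np.ndarray,
    grid_size: int = 512,
    min_separation: float = 0.2,
    min_values: int = 500,
) -> tuple[DensityFit, float]:
    """Fit the value density with two Gaussian peaks; threshold = intersect.

    The kernel density estimate (Gaussian kernel, Silverman bandwidth, grid
    spanning the data range ±3 bandwidths) is fitted by nonlinear least
    squares with a sum of two Gaussian peaks, initialized at the 25th/75th
    percentiles. The threshold is the component intersection between the two
    means. Non-convergence, means closer than ``min_separation``, or a
    missing interior root raise :class:`ThresholdFailure`.
    """
    values = np.asarray(values, dtype=float)
    if values.size < min_values:
        raise ThresholdFailure(f"need ≥ {min_values} values, got {values.size}")
    grid, density = _kde_curve(values, grid_size)

    q25, q75 = np.quantile(values, [0.25, 0.75])
    s0 = max(values.std(ddof=1) / 2.0, 1e-3)
    kde_at = np.interp([q25, q75], grid, density)
    p0 = [max(kde_at[0], 1e-6), q25, s0, max(kde_at[1], 1e-6), q75, s0]
    lo = [0.0, grid[0], 1e-4, 0.0, grid[0], 1e-4]
    hi = [np.inf, grid[-1], np.inf, np.inf, grid[-1], np.inf]

    def model(x, a1, m1, s1, a2, m2, s2):
        return _gauss(x, a1, m1, s1) + _gauss(x, a2, m2, s2)

    try:
        popt, _ = curve_fit(model, grid, density, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as err:
        raise ThresholdFailure(f"two-Gaussian fit did not converge: {err}") from err
    c1, c2 = (tuple(popt[:3]), tuple(popt[3:]))
    if c1[1] > c2[1]:
        c1, c2 = c2, c1
    if c2[1] - c1[1] < min_separation:
        raise ThresholdFailure(
            f"fitted means too close: {c1[1]:.3f} vs {c2[1]:.3f}"
        )
    residual = float(np.sum((model(grid, *popt) - density) ** 2))
    fit = DensityFit([c1, c2], grid, density, residual)
    threshold = gaussian_intersect(*c1, *c2)
    return fit, threshold


def fit_gaussian_mu_sigma(
    values: np.ndarray, grid_size: int = 512, min_values: int = 500
) -> tuple[DensityFit, float]:
    """Fit the value density with one Gaussian peak; threshold = μ + σ."""
    values = np.asarray(values, dtype=float)
    if values.size < min_values:
        raise ThresholdFailure(f"need ≥ {min_values} values, got {values.size}")
    grid, density = _kde_curve(values, grid_size)
    p0 = [density.max(), float(np.median(values)), max(values.std(ddof=1), 1e-3)]
    try:
        popt, _ = curve_fit(
            _gauss, grid, density, p0=p0,
            bounds=([0.0, grid[0], 1e-4], [np.inf, grid[-1], np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise ThresholdFailure(f"single-Gaussian fit did not converge: {err}") from err
    a, mu, sigma = popt
    residual = float(np.sum((_gauss(grid, *popt) - density) ** 2))
    fit = DensityFit([(a, mu, sigma)], grid, density, residual)
    return fit, float(mu + sigma)


def gate_naive_cd4(
    cd4_events: EventMatrix,
    cd45ra_marker: str = "CD45RA",
    fas_marker: str = "Fas",
) -> tuple[np.ndarray, ThresholdSet, dict[str, DensityFit]]:
    """Per-sample naive CD4 gate: CD45RA above its two-Gaussian intersect
    AND Fas below μ+σ fitted on the CD45RA-positive subset."""
    cd45ra = cd4_events.column(cd45ra_marker)
    fas = cd4_events.column(fas_marker)
    fit_ra, t_ra = fit_two_gaussian_intersect(cd45ra)
    fit_fas, t_fas = fit_gaussian_mu_sigma(fas[cd45ra > t_ra])
    thresholds = ThresholdSet()
    thresholds.set(cd45ra_marker, t_ra, "two_gaussian_intersect")
    thresholds.set(fas_marker, t_fas, "mu_plus_sigma")
    mask = (cd45ra > t_ra) & (fas < t_fas)
    return mask, thresholds, {cd45ra_marker: fit_ra, fas_marker: fit_fas}


# ---------------------------------------------------------------------------
# Naive-subset assignment
# ---------------------------------------------------------------------------

SUBSET_ORDER = (("CXCR3", "CXCR3hi"), ("CD38", "CD38++"), ("CD25", "CD25lo"))


def default_subset_thresholds() -> ThresholdSet:
    """Manual per-panel subset thresholds on the asinh scale.

    These play the role of the study's inspected per-panel threshold values;
    with the default generator they sit several population-σ away from both
    the negative and the positive modes of each marker.
    """
    t = ThresholdSet()
    t.set("CXCR3", 1.6, "manual")
    t.set("CD38", 1.8, "manual")
    t.set("CD25", 1.1, "manual")
    return t


def assign_naive_subsets(
    naive_events: EventMatrix,
    thresholds: ThresholdSet,
    include_cd25: bool = True,
) -> np.ndarray:
    """Sequential subset labels with strict precedence CXCR3 → CD38 → CD25.

    Events above the CXCR3 threshold are CXCR3hi; of the remainder, events
    above the CD38 threshold are CD38++; of the remainder (CD4 only), events
    above the CD25 threshold are CD25lo; leftovers are mature naive. The
    labels partition the naive events exactly.
    """
    labels = np.full(naive_events.n_events, "mature", dtype=object)
    unassigned = np.ones(naive_events.n_events, dtype=bool)
    for marker, label in SUBSET_ORDER:
        if marker == "CD25" and not include_cd25:
            continue
        if marker not in thresholds:
            raise KeyError(f"missing configured threshold for {marker}")
        hit = unassigned & (naive_events.column(marker) > thresholds[marker])
        labels[hit] = label
        unassigned &= ~hit
    return labels.astype(str)


def propose_cd38_threshold_from_ccr9(
    naive_events: EventMatrix,
    ccr9_threshold: float,
    ccr9_marker: str = "CCR9",
    cd38_marker: str = "CD38",
    quantile: float = 0.05,
) -> float:
    """Advisory CD38 threshold from a CCR9-positive reference.

    CCR9 marks recent thymic emigrants, so the low tail of CD38 among
    CCR9-positive naive cells approximates the CD38++ boundary when
    thymocyte controls are unavailable. The proposal is never applied
    automatically; it is returned for the analyst to adopt into config.
    """
    ccr9 = naive_events.column(ccr9_marker)
    ref = naive_events.column(cd38_marker)[ccr9 > ccr9_threshold]
    if ref.size == 0:
        raise ThresholdFailure("no CCR9-positive reference events")
    return float(np.quantile(ref, quantile))


# ---------------------------------------------------------------------------
# The gating tree and its runner
# ---------------------------------------------------------------------------

@dataclass
class GatingStep:
    """One cluster-and-select step of the hierarchical tree."""

    name: str
    parent: str | None
    markers_for_clustering: list[str]
    include_rules: list[MarkerRule] = field(default_factory=list)
    exclude_rules: list = field(default_factory=list)
    k: int = 30
    resolution: float = 1.0
    repeat: int = 1
    # optional complement bookkeeping (e.g. memory = clusters not selected)
    complement_name: str | None = None
    complement_exclude_rules: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.markers_for_clustering:
            raise ValueError(f"step {self.name}: empty clustering marker list")
        if self.repeat < 1:
            raise ValueError(f"step {self.name}: repeat must be ≥ 1")


@dataclass
class ThresholdGateStep:
    """Density-threshold gate (the naive-CD4 CD45RA/Fas construction)."""

    name: str
    parent: str | None
    cd45ra_marker: str = "CD45RA"
    fas_marker: str = "Fas"
    complement_name: str | None = None
    # event-level removals applied to the complement (marker, 'high'/'low', cut)
    complement_event_rules: list[tuple[str, str, float]] = field(default_factory=list)


def default_gating_tree() -> list:
    """The bundled hierarchical gating tree.

    Marker lists follow the study design step by step; selection rules use
    fixed asinh-scale thresholds near the positive/negative boundary (~1.5
    after a cofactor-3000 transform). Every rule and parameter is plain data
    and can be edited or replaced wholesale.
    """
    F = "fixed_threshold"
    lineage8 = ["CD3", "CD4", "CD8", "CD14", "CD19", "CD56", "CD25", "CD45RA"]
    return [
        GatingStep(
            "1_debris", None, ["FSC", "SSC", "LIVE_DEAD", "AF"],
            exclude_rules=[
                MarkerRule("LIVE_DEAD", "high", F, 2.0),
                MarkerRule("FSC", "low", F, 1.8),
            ],
            repeat=2,
        ),
        GatingStep(
            "2_tcells", "1_debris", lineage8,
            include_rules=[MarkerRule("CD3", "high", F, 1.5)],
        ),
        GatingStep(
            "3_cd8", "2_tcells", lineage8,
            include_rules=[MarkerRule("CD8", "high", F, 2.0)],
            exclude_rules=[MarkerRule("CD4", "high", F, 2.0)],
        ),
        GatingStep(
            "3_cd4", "2_tcells", lineage8,
            include_rules=[MarkerRule("CD4", "high", F, 2.0)],
            exclude_rules=[MarkerRule("CD8", "high", F, 2.0)],
        ),
        GatingStep(
            "4_1_naive_cd8", "3_cd8",
            ["Fas", "CD45RA", "KLRG1", "CX3CR1", "GzmB", "CD8", "GzmK", "CD27",
             "CD28", "CD56", "TRAV2", "gdTCR", "CCR7", "NKp80", "CD31", "CD4",
             "CCR4", "CD159c"],
            include_rules=[
                MarkerRule("CD45RA", "high", F, 2.0),
                MarkerRule("CCR7", "high", F, 2.0),
                MarkerRule("Fas", "low", F, 1.5),
            ],
            complement_name="memory_cd8",
            complement_exclude_rules=[
                MarkerRule("gdTCR", "high", F, 1.5),
                MarkerRule("TRAV2", "high", F, 1.5),
            ],
        ),
        GatingStep(
            "4_2_cd4", "3_cd4",
            ["CD4", "Fas", "CD45RA", "CD8", "CX3CR1", "gdTCR", "CD56", "CD14",
             "CD19", "CD3"],
            exclude_rules=[
                MarkerRule("gdTCR", "high", F, 1.5),
                [MarkerRule("GzmB", "high", F, 1.5),
                 MarkerRule("CD27", "low", F, 1.8)],
            ],
        ),
        ThresholdGateStep(
            "4_2a_naive_cd4", "4_2_cd4",
            complement_name="memory_cd4",
            complement_event_rules=[("gdTCR", "high", 1.5), ("CD25", "high", 2.2)],
        ),
        GatingStep(
            "4_2b_treg_removal", "4_2a_naive_cd4",
            ["CD4", "CD3", "CD45RA", "CXCR3", "Fas", "CD25", "CD127", "CD31"],
            exclude_rules=[
                [MarkerRule("CD25", "high", F, 2.2),
                 MarkerRule("CD127", "low", F, 1.2)],
            ],
        ),
        GatingStep("4_1a_final_cd8", "4_1_naive_cd8",
                   ["CD38", "CD25", "CD27", "CXCR3"]),
        GatingStep("4_2c_final_cd4", "4_2b_treg_removal",
                   ["CD38", "CD25", "CD27", "CXCR3"]),
    ]


@dataclass
class GatingResult:
    """Per-step event selections (masks over the donor's events) + audit."""

    donor_id: str
    masks: dict[str, np.ndarray]
    thresholds: dict[str, ThresholdSet]
    audit: list[dict]
    flags: list[str] = field(default_factory=list)

    def selection(self, name: str) -> np.ndarray:
        return self.masks[name]

    @property
    def naive_cd8(self) -> np.ndarray:
        return self.masks["4_1a_final_cd8"]

    @property
    def naive_cd4(self) -> np.ndarray:
        return self.masks["4_2c_final_cd4"]


def _step_seed(global_seed: int, donor_id: str, step_name: str) -> int:
    import zlib

    h = zlib.crc32(f"{donor_id}:{step_name}".encode())
    return int(np.random.SeedSequence([global_seed, h]).generate_state(1)[0] % (2**31))


def run_gating_tree(
    events: EventMatrix,
    tree: list | None = None,
    seed: int = 0,
    knn_method: str = "auto",
) -> GatingResult:
    """Execute the hierarchical gating tree on one donor's asinh matrix.

    Each step clusters only the events kept by its parent selection, on its
    own scaled marker subset, and keeps clusters passing its rules; events
    removed at a step never reappear downstream. Steps with ``repeat > 1``
    re-run their cluster-and-filter cycle on their own output. An empty
    selection flags the donor and skips dependent steps. The audit trail
    records, per step, the cluster profile, selected clusters and counts.
    """
    if events.scale != "asinh":
        raise ValueError("gating expects an asinh-scale matrix")
    tree = default_gating_tree() if tree is None else tree
    n = events.n_events
    masks: dict[str, np.ndarray] = {}
    thresholds: dict[str, ThresholdSet] = {}
    audit: list[dict] = []
    flags: list[str] = []

    cluster_cache: dict[tuple, tuple] = {}

    def parent_mask(step) -> np.ndarray | None:
        if step.parent is None:
            return np.ones(n, dtype=bool)
        if step.parent not in masks:
            return None  # parent skipped or failed
        return masks[step.parent]

    for step in tree:
        pmask = parent_mask(step)
        if pmask is None or not pmask.any():
            flags.append(f"{step.name}: parent selection empty, step skipped")
            continue
        if isinstance(step, ThresholdGateStep):
            sub = events.select_events(np.where(pmask)[0])
            try:
                mask_local, tset, _fits = gate_naive_cd4(
                    sub, step.cd45ra_marker, step.fas_marker
                )
            except ThresholdFailure as err:
                flags.append(f"{step.name}: {err}")
                continue
            sel = np.zeros(n, dtype=bool)
            sel[np.where(pmask)[0][mask_local]] = True
            masks[step.name] = sel
            thresholds[step.name] = tset
            if step.complement_name:
                comp = pmask & ~sel
                for marker, direction, cut in step.complement_event_rules:
                    col = events.column(marker)
                    bad = col > cut if direction == "high" else col < cut
                    comp &= ~bad
                masks[step.complement_name] = comp
            audit.append({
                "step": step.name, "donor_id": events.donor_id,
                "n_in": int(pmask.sum()), "n_selected": int(sel.sum()),
                "thresholds": dict(tset.thresholds),
            })
            continue

        current = pmask.copy()
        for rep in range(step.repeat):
            idx = np.where(current)[0]
            if idx.size <= step.k:
                flags.append(
                    f"{step.name}: only {idx.size} events (k={step.k}), step aborted"
                )
                current = None
                break
            sub = events.select_events(idx)
            # two sibling steps sharing parent/markers/params reuse one clustering
            shared_key = (idx.tobytes(), tuple(step.markers_for_clustering),
                          step.k, step.resolution,
                          _step_seed(seed, events.donor_id, f"{step.parent}-children#{rep}"))
            if shared_key in cluster_cache:
                labels = cluster_cache[shared_key]
            else:
                scaled, _ = scale_center(sub, step.markers_for_clustering)
                labels = cluster_events(
                    scaled, k=step.k, resolution=step.resolution,
                    seed=_step_seed(seed, events.donor_id,
                                    f"{step.parent}-children#{rep}"),
                    method=knn_method,
                )
                cluster_cache[shared_key] = labels
            profile = cluster_marker_profile(sub, labels)
            selected = select_clusters(profile, step.include_rules, step.exclude_rules)
            sel_local = np.isin(labels.labels, selected)
            audit.append({
                "step": step.name, "donor_id": events.donor_id, "repeat": rep,
                "n_in": int(idx.size), "n_clusters": labels.n_clusters,
                "selected_clusters": selected,
                "n_selected": int(sel_local.sum()),
                "modularity": labels.modularity,
                "cluster_sizes": profile.sizes.tolist(),
            })
            if step.complement_name and rep == step.repeat - 1:
                comp_clusters = select_clusters(
                    profile,
                    include_rules=[],
                    exclude_rules=step.complement_exclude_rules,
                )
                comp_ids = [c for c in comp_clusters if c not in selected]
                comp = np.zeros(n, dtype=bool)
                comp[idx[np.isin(labels.labels, comp_ids)]] = True
                masks[step.complement_name] = comp
            nxt = np.zeros(n, dtype=bool)
            nxt[idx[sel_local]] = True
            if not nxt.any():
                flags.append(f"{step.name}: empty selection, donor flagged")
                current = None
                break
            current = nxt
        if current is not None:
            masks[step.name] = current

    return GatingResult(
        donor_id=events.donor_id, masks=masks, thresholds=thresholds,
        audit=audit, flags=flags,
    )
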