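"""Synthetic spectral-cytometry cohort generator with ground-truth labels.

The generator emulates the statistical structure the gating pipeline assumes:
each donor is a mixture of labeled cell populations (debris, doublets, dead
cells, monocytes, B cells, NK cells, γδ T cells, MAIT cells, memory and naive
CD8+/CD4+ T cells, Tregs, and naive subsets CD38++, CXCR3hi, CD25lo, mature)
whose mixing fractions vary deterministically with donor age and whose marker
intensities are Gaussian per population on the asinh scale. Raw-scale values
are produced by the exact inverse of the variance-stabilizing transform,
``x_raw = sinh(y) * cofactor``, so that ``asinh(x_raw / cofactor)`` recovers
the latent draws.

Doublets are element-wise maxima of two sampled viable singlet events; dead
cells carry a high viability-dye (LIVE_DEAD) signal; debris sits low on the
scatter analogs (FSC/SSC). These give the quality-control gate real events
to remove.

The default cohort reproduces the aging-study conditions: 158 donors in five
10-year age groups A–E (sizes 45/29/21/28/35, ages 25–85), a 30-marker panel,
~1.2e5 events per donor, cofactor 3000, a CD38++ (recent thymic emigrant)
fraction that declines linearly with age and CXCR3hi / CD25lo fractions that
rise with age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .events import EventMatrix

__all__ = [
    "PopulationSpec",
    "CohortConfig",
    "DonorSample",
    "linear_freq",
    "default_panel",
    "default_populations",
    "default_cohort_config",
    "sample_donor_ages",
    "population_frequencies",
    "leaf_frequencies",
    "simulate_donor",
    "simulate_cohort",
    "simulate_proportion_cohort",
    "write_cohort",
    "NAIVE_SUBSET_OF",
]


class ConfigurationError(ValueError):
    pass


def linear_freq(f0: float, slope: float, a0: float = 25.0) -> Callable[[float], float]:
    """Linear age template ``f(a) = f0 + slope * (a - a0)``, clipped at 0."""

    def f(age: float) -> float:
        return max(0.0, f0 + slope * (age - a0))

    return f


@dataclass
class PopulationSpec:
    """One labeled population in the hierarchical mixture.

    ``freq_fn`` maps age (years) to the expected fraction of the *parent*
    population; ``None`` marks the parent's residual child, which absorbs
    whatever fraction its siblings leave. ``kind`` is ``gaussian`` for
    ordinary populations, ``doublet`` for element-wise-max aggregates.
    Marker means/sds are on the asinh scale; markers absent from the maps
    fall back to the panel baseline (dim negative signal).
    """

    name: str
    parent: str | None
    marker_means: dict[str, float] = field(default_factory=dict)
    marker_sds: dict[str, float] = field(default_factory=dict)
    freq_fn: Callable[[float], float] | None = None
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        for m, sd in self.marker_sds.items():
            if sd <= 0:
                raise ConfigurationError(f"{self.name}: sd for {m} must be > 0")


@dataclass
class CohortConfig:
    n_donors: int
    age_groups: list[tuple[str, float, float]]
    group_sizes: list[int]
    panel: list[str]
    populations: list[PopulationSpec]
    events_per_donor: int = 120_000
    cofactor: float = 3000.0
    seed: int = 0
    baseline_mean: float = 0.35
    baseline_sd: float = 0.25

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_donors:
            raise ConfigurationError(
                f"group sizes {self.group_sizes} do not sum to n_donors={self.n_donors}"
            )
        if len(self.group_sizes) != len(self.age_groups):
            raise ConfigurationError("one size per age group required")
        ivals = sorted((lo, hi) for _, lo, hi in self.age_groups)
        for (lo1, hi1), (lo2, _) in zip(ivals, ivals[1:]):
            if lo2 < hi1:
                raise ConfigurationError("age-group intervals overlap")
        panel = set(self.panel)
        for pop in self.populations:
            missing = (set(pop.marker_means) | set(pop.marker_sds)) - panel
            if missing:
                raise ConfigurationError(
                    f"population {pop.name} references markers not in panel: {sorted(missing)}"
                )
        if self.cofactor <= 0:
            raise ConfigurationError("cofactor must be positive")


@dataclass
class DonorSample:
    """One simulated donor: raw-scale events plus per-event truth labels."""

    donor_id: str
    age: float
    group: str
    events: EventMatrix
    truth: np.ndarray
    latent_asinh: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.truth) != self.events.n_events:
            raise ValueError("truth labels must align with event rows")


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

TECHNICAL_MARKERS = ["FSC", "SSC", "LIVE_DEAD", "AF"]

#: leaf label → naive parent ("cd8_naive" / "cd4_naive") for truth bookkeeping
NAIVE_SUBSET_OF = {
    "cd8_naive_cd38": "cd8_naive",
    "cd8_naive_cxcr3": "cd8_naive",
    "cd8_naive_mature": "cd8_naive",
    "cd4_naive_cd38": "cd4_naive",
    "cd4_naive_cxcr3": "cd4_naive",
    "cd4_naive_cd25": "cd4_naive",
    "cd4_naive_mature": "cd4_naive",
}


def default_panel() -> list[str]:
    return TECHNICAL_MARKERS + [
        "CD3", "CD4", "CD8", "CD14", "CD19", "CD56",
        "CD45RA", "CCR7", "Fas", "CD25", "CD127", "CD27", "CD28",
        "CD38", "CXCR3", "gdTCR", "TRAV2", "CD31", "PTK7",
        "KLRG1", "CX3CR1", "GzmB", "GzmK", "NKp80", "CCR4", "CD159c",
    ]


def _viable(**means: float) -> dict[str, float]:
    base = {"FSC": 3.0, "SSC": 1.9, "LIVE_DEAD": 0.4, "AF": 0.8}
    base.update(means)
    return base


def default_populations() -> list[PopulationSpec]:
    """The default labeled mixture. Means are asinh-scale; positives sit near
    3, dim positives near 1.5–2, negatives near the 0.35 baseline."""
    tcell = {"CD3": 3.2}
    naive8 = _viable(**tcell, CD8=3.0, CD45RA=3.2, CCR7=2.8, Fas=0.5,
                     CD27=2.8, CD28=2.5, CD31=2.0, CD127=2.2)
    naive4 = _viable(**tcell, CD4=3.0, CD45RA=3.2, CCR7=2.8, Fas=0.5,
                     CD27=2.8, CD28=2.8, CD31=2.0, CD127=2.5)
    pops = [
        PopulationSpec("debris", None,
                       {"FSC": 0.8, "SSC": 0.6, "LIVE_DEAD": 0.5, "AF": 0.6},
                       {"FSC": 0.4, "SSC": 0.4},
                       linear_freq(0.03, 0.0)),
        PopulationSpec("doublet", None, {}, {}, linear_freq(0.02, 0.0),
                       kind="doublet"),
        PopulationSpec("dead", None,
                       _viable(LIVE_DEAD=3.0, FSC=2.8, SSC=2.3),
                       {"LIVE_DEAD": 0.4},
                       linear_freq(0.04, 0.0)),
        PopulationSpec("monocyte", None,
                       _viable(CD14=3.0, CD4=1.2, SSC=2.8, FSC=3.3, AF=1.5),
                       {}, linear_freq(0.18, 0.0)),
        PopulationSpec("bcell", None, _viable(CD19=3.0, CD27=1.0),
                       {}, linear_freq(0.10, 0.0)),
        PopulationSpec("nk", None, _viable(CD56=3.0, CD8=1.0, NKp80=2.5,
                                           GzmB=2.2, Fas=1.8),
                       {}, linear_freq(0.08, 0.0)),
        PopulationSpec("gdt", None,
                       _viable(**tcell, gdTCR=3.0, CD8=1.0, CD45RA=2.0, Fas=1.5),
                       {}, linear_freq(0.02, 0.0)),
        PopulationSpec("mait", None,
                       _viable(**tcell, TRAV2=3.0, CD8=2.0, Fas=2.0,
                               CCR7=1.0, CD45RA=1.0),
                       {}, linear_freq(0.02, 0.0)),
        PopulationSpec("cd8_mem", None,
                       _viable(**tcell, CD8=3.0, CD45RA=0.8, CCR7=0.8, Fas=2.5,
                               GzmB=2.2, GzmK=2.0, KLRG1=2.0, CX3CR1=1.8,
                               CD27=1.5, CD28=1.5),
                       {"CD45RA": 0.4},
                       linear_freq(0.10, 0.0008)),
        PopulationSpec("cd8_naive", None, naive8, {},
                       linear_freq(0.09, -0.0008)),
        PopulationSpec("treg", None,
                       _viable(**tcell, CD4=3.0, CD25=3.0, CD127=0.4,
                               CD45RA=2.8, Fas=0.6, CCR7=2.5, CD31=1.5),
                       {}, linear_freq(0.02, 0.0)),
        PopulationSpec("cd4_mem", None,
                       _viable(**tcell, CD4=3.0, CD45RA=0.8, CCR7=1.2, Fas=2.5,
                               CD127=2.0, CD27=2.0, CXCR3=1.2),
                       {"CD45RA": 0.4},
                       None),  # residual of the root
        PopulationSpec("cd4_naive", None, naive4, {},
                       linear_freq(0.13, 0.0)),
        # naive CD8 subsets -------------------------------------------------
        PopulationSpec("cd8_naive_cd38", "cd8_naive",
                       {**naive8, "CD38": 3.0, "PTK7": 2.0, "CD31": 2.5},
                       {}, linear_freq(0.06, -0.0006)),
        PopulationSpec("cd8_naive_cxcr3", "cd8_naive",
                       {**naive8, "CXCR3": 2.8, "CD38": 0.5},
                       {}, linear_freq(0.04, 0.0008)),
        PopulationSpec("cd8_naive_mature", "cd8_naive",
                       {**naive8, "CD38": 0.5, "CXCR3": 0.45},
                       {}, None),
        # naive CD4 subsets -------------------------------------------------
        PopulationSpec("cd4_naive_cd38", "cd4_naive",
                       {**naive4, "CD38": 3.0, "PTK7": 2.0, "CD31": 2.5},
                       {}, linear_freq(0.06, -0.0006)),
        PopulationSpec("cd4_naive_cxcr3", "cd4_naive",
                       {**naive4, "CXCR3": 2.8, "CD38": 0.5},
                       {}, linear_freq(0.04, 0.0008)),
        PopulationSpec("cd4_naive_cd25", "cd4_naive",
                       {**naive4, "CD25": 1.8, "CD38": 0.5},
                       {"CD25": 0.25}, linear_freq(0.05, 0.001)),
        PopulationSpec("cd4_naive_mature", "cd4_naive",
                       {**naive4, "CD38": 0.5, "CXCR3": 0.45, "CD25": 0.4},
                       {"CD25": 0.25}, None),
    ]
    return pops


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    kwargs = dict(
        n_donors=158,
        age_groups=[("A", 25.0, 35.0), ("B", 35.0, 45.0), ("C", 45.0, 55.0),
                    ("D", 55.0, 65.0), ("E", 65.0, 85.0)],
        group_sizes=[45, 29, 21, 28, 35],
        panel=default_panel(),
        populations=default_populations(),
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def population_frequencies(
    age: float, populations: Sequence[PopulationSpec]
) -> dict[str, float]:
    """Expected fraction-of-parent for every population at the given age.

    Within each sibling set the residual child (freq_fn=None) absorbs
    ``1 - sum(siblings)``; siblings summing above 1 or a negative freq_fn
    value is a specification error.
    """
    by_parent: dict[str | None, list[PopulationSpec]] = {}
    for pop in populations:
        by_parent.setdefault(pop.parent, []).append(pop)
    out: dict[str, float] = {}
    for parent, sibs in by_parent.items():
        residuals = [p for p in sibs if p.freq_fn is None]
        if len(residuals) > 1:
            raise ConfigurationError(f"multiple residual children under {parent!r}")
        total = 0.0
        for p in sibs:
            if p.freq_fn is None:
                continue
            f = p.freq_fn(age)
            if f < 0:
                raise ConfigurationError(f"{p.name}: negative frequency at age {age}")
            out[p.name] = f
            total += f
        if total > 1 + 1e-12:
            raise ConfigurationError(
                f"children of {parent!r} sum to {total:.4f} > 1 at age {age}"
            )
        if residuals:
            out[residuals[0].name] = 1.0 - total
    return out


def leaf_frequencies(
    age: float, populations: Sequence[PopulationSpec]
) -> dict[str, float]:
    """Absolute fraction of all events for every leaf population."""
    rel = population_frequencies(age, populations)
    parents = {p.name: p.parent for p in populations}
    has_children = {p.parent for p in populations if p.parent is not None}

    def absolute(name: str) -> float:
        f = rel[name]
        parent = parents[name]
        while parent is not None:
            f *= rel[parent]
            parent = parents[parent]
        return f

    return {p.name: absolute(p.name) for p in populations if p.name not in has_children}


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_donor_ages(config: CohortConfig) -> list[tuple[str, float, str]]:
    """Draw (donor_id, age, group) for the whole cohort, uniform within each
    group's interval, deterministic given the config seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    out: list[tuple[str, float, str]] = []
    for (label, lo, hi), size in zip(config.age_groups, config.group_sizes):
        ages = rng.uniform(lo, hi, size=size)
        for i, age in enumerate(ages, start=1):
            out.append((f"{label}{i:03d}", float(age), label))
    return out


def _population_params(
    config: CohortConfig,
) -> tuple[list[str], np.ndarray, np.ndarray, dict[str, int]]:
    """Per-leaf mean/sd matrices over the full panel (gaussian leaves only)."""
    pops = {p.name: p for p in config.populations}
    has_children = {p.parent for p in config.populations if p.parent is not None}
    leaves = [p for p in config.populations if p.name not in has_children]
    names, means, sds = [], [], []
    for p in leaves:
        names.append(p.name)
        mu = np.full(len(config.panel), config.baseline_mean)
        sd = np.full(len(config.panel), config.baseline_sd)
        for j, marker in enumerate(config.panel):
            if marker in p.marker_means:
                mu[j] = p.marker_means[marker]
            if marker in p.marker_sds:
                sd[j] = p.marker_sds[marker]
            elif marker in p.marker_means:
                sd[j] = 0.30
        means.append(mu)
        sds.append(sd)
    kind = {p.name: p.kind for p in config.populations}
    return names, np.array(means), np.array(sds), kind


def simulate_donor(
    meta: tuple[str, float, str],
    config: CohortConfig,
    n_events: int | None = None,
    seed: int | None = None,
) -> DonorSample:
    """Simulate one donor's raw-scale event matrix with truth labels.

    Per-event labels are drawn from the age-dependent leaf frequencies;
    gaussian leaves draw independent per-marker normals on the asinh scale;
    doublets take the element-wise max of two viable singlet draws. Raw
    values are ``sinh(y) * cofactor``. Deterministic given the seed.
    """
    donor_id, age, group = meta
    if n_events is None:
        n_events = config.events_per_donor
    if n_events <= 0:
        raise ConfigurationError("n_events must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    freqs = leaf_frequencies(age, config.populations)
    names, means, sds, kind = _population_params(config)
    p = np.array([freqs[n] for n in names])
    p = p / p.sum()  # guard float drift; components already sum to 1
    idx = rng.choice(len(names), size=n_events, p=p)

    latent = np.empty((n_events, len(config.panel)))
    # singlet pool for doublet construction: viable cell populations
    singlet_mask = np.array(
        [kind[n] == "gaussian" and n not in ("debris", "dead") for n in names]
    )
    singlet_p = p * singlet_mask
    singlet_p = singlet_p / singlet_p.sum()
    for i, name in enumerate(names):
        rows = np.where(idx == i)[0]
        if rows.size == 0:
            continue
        if kind[name] == "doublet":
            src = rng.choice(len(names), size=(rows.size, 2), p=singlet_p)
            a = rng.normal(means[src[:, 0]], sds[src[:, 0]])
            b = rng.normal(means[src[:, 1]], sds[src[:, 1]])
            latent[rows] = np.maximum(a, b)
        else:
            latent[rows] = rng.normal(
                means[i], sds[i], size=(rows.size, len(config.panel))
            )

    raw = np.sinh(latent) * config.cofactor
    events = EventMatrix(raw, config.panel, donor_id=donor_id, scale="raw")
    truth = np.array([names[i] for i in idx])
    return DonorSample(donor_id, age, group, events, truth, latent_asinh=latent)


def simulate_cohort(
    config: CohortConfig, n_events: int | None = None
) -> list[DonorSample]:
    """Simulate every donor in the cohort; per-donor seeds are spawned from
    the config seed so the cohort is fully reproducible."""
    metas = sample_donor_ages(config)
    out = []
    for i, meta in enumerate(metas):
        seed = np.random.SeedSequence([config.seed, 1, i])
        out.append(simulate_donor(meta, config, n_events=n_events,
                                  seed=np.random.default_rng(seed).integers(2**31)))
    return out


def simulate_proportion_cohort(
    config: CohortConfig,
    naive_events_per_donor: int = 5000,
    null: bool = False,
    null_age: float = 45.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Donor-level naive-subset proportions drawn from the same frequency
    model as the event-level generator, for statistical calibration runs.

    For each donor and each naive parent (cd8_naive / cd4_naive), subset
    counts are multinomial draws of size ``naive_events_per_donor`` at the
    donor's age-dependent subset frequencies (or at a fixed age under the
    null, removing the age effect). Returns a tidy frame with one row per
    donor × subset.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    metas = sample_donor_ages(config)
    pops = {p.name: p for p in config.populations}
    cols = {k: [] for k in ("donor_id", "age", "group", "parent", "subset",
                            "numerator")}
    n = naive_events_per_donor
    for donor_id, age, group in metas:
        freq_age = null_age if null else age
        rel = population_frequencies(freq_age, config.populations)
        for parent in ("cd8_naive", "cd4_naive"):
            subsets = [s for s, par in NAIVE_SUBSET_OF.items()
                       if par == parent and s in pops]
            probs = np.array([rel[s] for s in subsets])
            counts = rng.multinomial(n, probs / probs.sum())
            cols["donor_id"] += [donor_id] * len(subsets)
            cols["age"] += [age] * len(subsets)
            cols["group"] += [group] * len(subsets)
            cols["parent"] += [parent] * len(subsets)
            cols["subset"] += subsets
            cols["numerator"] += counts.tolist()
    frame = pd.DataFrame(cols)
    frame["denominator"] = n
    frame["proportion"] = frame["numerator"] / n
    return frame


def write_cohort(samples: Sequence[DonorSample], out_dir) -> pd.DataFrame:
    """Write per-donor events as CSV, truth labels as TSV sidecars, and a
    cohort manifest TSV; returns the manifest frame."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        events_path = out / f"{s.donor_id}_events.csv"
        truth_path = out / f"{s.donor_id}_truth.tsv"
        s.events.to_csv(events_path)
        pd.DataFrame(
            {"event_index": np.arange(len(s.truth)), "label": s.truth}
        ).to_csv(truth_path, sep="\t", index=False)
        rows.append({"donor_id": s.donor_id, "age": s.age, "group": s.group,
                     "events_file": events_path.name, "truth_file": truth_path.name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
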