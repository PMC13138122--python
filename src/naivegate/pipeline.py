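"""End-to-end orchestration: simulate/load → preprocess → gate → statistics.

One :class:`PipelineConfig` drives the whole run. Per-donor work is
isolated — a failing donor is recorded in the run manifest without touching
other donors' outputs — and every output table carries the config hash and
global seed, so identical configs reproduce identical tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate as sim
from .events import EventMatrix
from .gating import (
    GatingResult,
    ThresholdSet,
    default_gating_tree,
    assign_naive_subsets,
    run_gating_tree,
)
from .preprocess import (
    InsufficientEventsError,
    asinh_transform,
    qc_exclude,
    subsample_events,
)
from .stats import (
    age_trend,
    bonferroni_by_subpopulations,
    mfi_median,
    subset_proportions,
    subset_group_test,
)

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for one full pipeline run.

    Either ``input_dir`` points at a cohort written by
    :func:`naivegate.simulate.write_cohort` (manifest.tsv + per-donor CSVs),
    or ``simulate=True`` generates a cohort in memory from the bundled
    synthetic model.
    """

    out_dir: str = "naivegate_run"
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    n_donors: int = 158
    group_sizes: list[int] = field(default_factory=lambda: [45, 29, 21, 28, 35])
    events_per_donor: int = 120_000
    cofactor: float = 3000.0
    subsample_n: int = 100_000
    min_naive_cd8: int = 200
    knn_method: str = "auto"
    subset_thresholds: dict[str, float] = field(
        default_factory=lambda: {"CXCR3": 1.6, "CD38": 1.8, "CD25": 1.1}
    )
    write_labels: bool = False

    def config_hash(self) -> str:
        # out_dir is where results land, not what they are
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    donors: dict[str, dict]
    outputs: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect configuration violations (empty list = valid)."""
    v: list[str] = []
    if config.cofactor <= 0:
        v.append("cofactor: must be positive")
    if config.subsample_n <= 0:
        v.append("subsample_n: must be positive")
    if not config.simulate and config.input_dir is None:
        v.append("input_dir: required when simulate is false")
    if config.simulate and sum(config.group_sizes) != config.n_donors:
        v.append(
            f"group_sizes: sum {sum(config.group_sizes)} != n_donors {config.n_donors}"
        )
    for marker in ("CXCR3", "CD38", "CD25"):
        if marker not in config.subset_thresholds:
            v.append(f"subset_thresholds: missing {marker}")
    panel = set(sim.default_panel())
    for step in default_gating_tree():
        markers = getattr(step, "markers_for_clustering", [])
        for m in markers:
            if m not in panel:
                v.append(f"gating step {step.name}: marker {m} not in panel")
    return v


def _donor_seed(global_seed: int, donor_id: str, stage: str) -> int:
    h = zlib.crc32(f"{donor_id}/{stage}".encode())
    return int(np.random.SeedSequence([global_seed, h]).generate_state(1)[0] % (2**31))


def _load_cohort(config: PipelineConfig):
    """Yield (donor_id, age, group, loader) where loader() returns the raw
    EventMatrix; deferring the load keeps per-donor read failures isolated."""
    if config.simulate:
        cohort_config = sim.default_cohort_config(
            seed=config.seed,
            n_donors=config.n_donors,
            group_sizes=config.group_sizes,
            events_per_donor=config.events_per_donor,
            cofactor=config.cofactor,
        )

        def simulate_loader(meta):
            return lambda: sim.simulate_donor(
                meta, cohort_config,
                seed=_donor_seed(config.seed, meta[0], "simulate"),
            ).events

        for meta in sim.sample_donor_ages(cohort_config):
            yield meta[0], meta[1], meta[2], simulate_loader(meta)
    else:
        root = Path(config.input_dir)
        manifest = pd.read_csv(root / "manifest.tsv", sep="\t")

        def csv_loader(path, donor_id):
            return lambda: EventMatrix.from_csv(path, donor_id=donor_id, scale="raw")

        for row in manifest.itertuples():
            yield (row.donor_id, float(row.age), row.group,
                   csv_loader(root / row.events_file, row.donor_id))


def _gate_donor(
    config: PipelineConfig, donor_id: str, events_raw: EventMatrix
) -> tuple[GatingResult, dict[str, np.ndarray], EventMatrix]:
    """Subsample → transform → gate → assign subsets for one donor."""
    sub = subsample_events(
        events_raw, n=config.subsample_n,
        seed=_donor_seed(config.seed, donor_id, "subsample"),
    )
    asinh = asinh_transform(sub, cofactor=config.cofactor)
    result = run_gating_tree(
        asinh, seed=config.seed, knn_method=config.knn_method
    )
    tset = ThresholdSet()
    for marker, value in config.subset_thresholds.items():
        tset.set(marker, value, "manual")
    labels: dict[str, np.ndarray] = {}
    for parent, mask_name, with_cd25 in (
        ("naive_cd8", "4_1a_final_cd8", False),
        ("naive_cd4", "4_2c_final_cd4", True),
    ):
        if mask_name not in result.masks:
            continue
        naive = asinh.select_events(np.where(result.masks[mask_name])[0])
        labels[parent] = assign_naive_subsets(naive, tset, include_cd25=with_cd25)
    return result, labels, asinh


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full pipeline and write all stage outputs under ``out_dir``.

    Outputs: ``proportions.tsv`` (tidy per-donor subset proportions),
    ``tests.tsv`` (Kruskal–Wallis + Dunn/Holm/Bonferroni per subset),
    ``trends.tsv`` (Pearson age trends), ``qc.tsv``, ``fas_mfi.tsv``,
    ``audit.jsonl`` and ``manifest.json``.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    donor_status: dict[str, dict] = {}
    meta_rows, label_store, mfi_rows, naive_cd8_counts = [], {}, [], {}
    audit_path = out / "audit.jsonl"
    with open(audit_path, "w") as audit_fh:
        for donor_id, age, group, load_events in _load_cohort(config):
            try:
                events_raw = load_events()
                if events_raw.n_events < config.subsample_n:
                    donor_status[donor_id] = {
                        "status": "excluded", "reason": "insufficient_events",
                        "n_events": events_raw.n_events,
                    }
                    continue
                result, labels, asinh = _gate_donor(config, donor_id, events_raw)
                for record in result.audit:
                    audit_fh.write(json.dumps(record, sort_keys=True) + "\n")
                n_naive_cd8 = int(labels.get("naive_cd8", np.array([])).size)
                naive_cd8_counts[donor_id] = n_naive_cd8
                if n_naive_cd8 < config.min_naive_cd8:
                    donor_status[donor_id] = {
                        "status": "excluded", "reason": "insufficient_naive_cd8",
                        "n_naive_cd8": n_naive_cd8,
                    }
                    continue
                meta_rows.append({"donor_id": donor_id, "age": age, "group": group})
                for parent, lab in labels.items():
                    label_store.setdefault(parent, {})[donor_id] = lab
                for parent, mem_name in (
                    ("naive_cd8", "memory_cd8"), ("naive_cd4", "memory_cd4"),
                ):
                    gate_name = ("4_1a_final_cd8" if parent == "naive_cd8"
                                 else "4_2c_final_cd4")
                    if gate_name in result.masks:
                        mfi_rows.append({
                            "donor_id": donor_id, "age": age, "group": group,
                            "compartment": parent, "population": "naive",
                            "fas_mfi": mfi_median(asinh, "Fas",
                                                  result.masks[gate_name]),
                        })
                    if mem_name in result.masks:
                        mfi_rows.append({
                            "donor_id": donor_id, "age": age, "group": group,
                            "compartment": parent, "population": "memory",
                            "fas_mfi": mfi_median(asinh, "Fas",
                                                  result.masks[mem_name]),
                        })
                donor_status[donor_id] = {
                    "status": "processed", "flags": result.flags,
                    "n_naive_cd8": n_naive_cd8,
                }
                if config.write_labels:
                    for parent, lab in labels.items():
                        pd.DataFrame({"label": lab}).to_csv(
                            out / f"{donor_id}_{parent}_labels.tsv",
                            sep="\t", index=False,
                        )
            except InsufficientEventsError:
                donor_status[donor_id] = {
                    "status": "excluded", "reason": "insufficient_events",
                }
            except Exception as err:  # crash isolation per donor
                donor_status[donor_id] = {
                    "status": "failed", "stage": type(err).__name__,
                    "error": str(err),
                }

    qc = qc_exclude(
        {d: (config.subsample_n
             if donor_status[d].get("status") != "excluded"
             or donor_status[d].get("reason") != "insufficient_events"
             else donor_status[d].get("n_events", 0))
         for d in donor_status},
        naive_cd8_counts,
        min_events=config.subsample_n,
        min_naive_cd8=config.min_naive_cd8,
    )
    qc_frame = pd.DataFrame(
        [{"donor_id": d, "status": "excluded", "reason": r} for d, r in qc.excluded]
        + [{"donor_id": d, "status": "retained", "reason": ""} for d in qc.retained]
    ).sort_values("donor_id")

    meta = pd.DataFrame(meta_rows)
    tables, test_frames, trend_rows = [], [], []
    for parent, per_donor in sorted(label_store.items()):
        table = subset_proportions(per_donor, meta)
        table.insert(0, "parent", parent)
        tables.append(table)
        subsets = sorted(table["subset"].unique())
        results = []
        for s in subsets:
            try:
                results.append(subset_group_test(table, s))
            except ValueError:
                # fewer than two age groups retained for this subset
                continue
        bonferroni_by_subpopulations(results, m=len(subsets))
        for res in results:
            frame = res.to_frame()
            frame.insert(0, "parent", parent)
            test_frames.append(frame)
        for s in subsets:
            sub = table[(table["subset"] == s) & table["proportion"].notna()]
            if len(sub) >= 3 and sub["proportion"].nunique() > 1:
                tr = age_trend(sub["proportion"].to_numpy() * 100.0,
                               sub["age"].to_numpy())
                trend_rows.append({
                    "parent": parent, "subset": s, "r": tr.r, "p": tr.p,
                    "slope": tr.slope, "intercept": tr.intercept, "n": tr.n,
                })

    def _write(frame: pd.DataFrame, name: str) -> str:
        frame = frame.copy()
        frame["config_hash"] = chash
        frame["seed"] = config.seed
        frame.to_csv(out / name, sep="\t", index=False, float_format="%.10g")
        return name

    outputs = [
        _write(pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(),
               "proportions.tsv"),
        _write(pd.concat(test_frames, ignore_index=True) if test_frames
               else pd.DataFrame(), "tests.tsv"),
        _write(pd.DataFrame(trend_rows), "trends.tsv"),
        _write(qc_frame, "qc.tsv"),
        _write(pd.DataFrame(mfi_rows), "fas_mfi.tsv"),
        "audit.jsonl",
    ]
    manifest = RunManifest(
        config_hash=chash, seed=config.seed, donors=donor_status, outputs=outputs
    )
    manifest.to_json(out / "manifest.json")
    return manifest
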