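"""Intensity transform, event subsampling and donor-level quality control.

Raw unmixed intensities are variance-stabilized with ``asinh(x / cofactor)``
(cofactor 3000 by default), each file is subsampled to a fixed event count
(100,000 by default) to balance donor contributions, and donors failing
either the event-count floor or the minimum naive-CD8 count are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .events import EventMatrix, ScaleError

DEFAULT_COFACTOR = 3000.0
DEFAULT_SUBSAMPLE_N = 100_000
DEFAULT_MIN_NAIVE_CD8 = 200


class InsufficientEventsError(ValueError):
    """A donor has fewer events than the requested subsample size."""


def asinh_transform(m: EventMatrix, cofactor: float = DEFAULT_COFACTOR) -> EventMatrix:
    """Apply ``y = asinh(x / cofactor)`` entry-wise to a raw matrix.

    Strictly monotone per entry and exactly invertible via
    ``x = sinh(y) * cofactor``. By default all channels, including scatter
    and viability analogs, are transformed identically.
    """
    if m.scale != "raw":
        raise ScaleError(f"asinh_transform expects a raw matrix, got {m.scale!r}")
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return replace(
        m, values=np.arcsinh(m.values / cofactor), scale="asinh", cofactor=cofactor
    )


def inverse_asinh(m: EventMatrix) -> EventMatrix:
    """Invert the asinh transform back to the raw scale."""
    if m.scale != "asinh":
        raise ScaleError(f"inverse_asinh expects an asinh matrix, got {m.scale!r}")
    return replace(m, values=np.sinh(m.values) * m.cofactor, scale="raw", cofactor=None)


def subsample_events(
    m: EventMatrix, n: int = DEFAULT_SUBSAMPLE_N, seed: int = 0
) -> EventMatrix:
    """Return exactly ``n`` rows sampled uniformly without replacement.

    A donor with fewer than ``n`` events raises
    :class:`InsufficientEventsError` rather than being silently truncated —
    such donors are excluded from the study.
    """
    if m.n_events < n:
        raise InsufficientEventsError(
            f"donor {m.donor_id!r} has {m.n_events} events < required {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(m.n_events, size=n, replace=False)
    return m.select_events(idx)


@dataclass
class QCReport:
    """Exhaustive donor-level exclusion report."""

    excluded: list[tuple[str, str]]
    retained: list[str]
    parameters: dict

    def __post_init__(self) -> None:
        dropped = {d for d, _ in self.excluded}
        if dropped & set(self.retained):
            raise ValueError("a donor cannot be both excluded and retained")


def qc_exclude(
    event_counts: dict[str, int],
    naive_cd8_counts: dict[str, int] | None = None,
    min_events: int = DEFAULT_SUBSAMPLE_N,
    min_naive_cd8: int = DEFAULT_MIN_NAIVE_CD8,
) -> QCReport:
    """Apply the two donor-exclusion criteria.

    ``insufficient_events`` drops donors below the subsample floor;
    ``insufficient_naive_cd8`` drops technical outliers whose naive CD8+
    count (available only after gating) is too small for stable statistics.
    """
    excluded, retained = [], []
    for donor, n in event_counts.items():
        if n < min_events:
            excluded.append((donor, "insufficient_events"))
        elif (
            naive_cd8_counts is not None
            and donor in naive_cd8_counts
            and naive_cd8_counts[donor] < min_naive_cd8
        ):
            excluded.append((donor, "insufficient_naive_cd8"))
        else:
            retained.append(donor)
    return QCReport(
        excluded=excluded,
        retained=retained,
        parameters={"min_events": min_events, "min_naive_cd8": min_naive_cd8},
    )


def scale_center(
    m: EventMatrix, markers: list[str] | None = None
) -> tuple[EventMatrix, list[str]]:
    """Z-score the selected asinh-scale columns (mean 0, sample sd 1).

    Columns not requested are dropped. Zero-variance columns are set to all
    zeros and reported in the returned warning list instead of producing NaN.
    """
    if m.scale != "asinh":
        raise ScaleError(f"scale_center expects an asinh matrix, got {m.scale!r}")
    sel = m.select_markers(markers) if markers is not None else m
    values = sel.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(values.shape[1])
    warnings = [sel.markers[j] for j in np.where(sd == 0)[0]]
    safe_sd = np.where(sd == 0, 1.0, sd)
    scaled = (values - mean) / safe_sd
    scaled[:, sd == 0] = 0.0
    return replace(sel, values=scaled, scale="scaled"), warnings
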