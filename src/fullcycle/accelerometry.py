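"""Tri-axial acceleration bursts: baseline removal, dynamic body acceleration,
and reduction of classifier labels to the four behavior modes used downstream.

A burst is one second of surge/sway/heave acceleration recorded after a GPS fix
(20 samples at 20 Hz on the tags this pipeline targets, though any rate with at
least two samples is accepted). Dynamic body acceleration (DBA) is computed the
VeDBA way: the static (gravitational) baseline is removed per axis, then the
per-sample vector norms are averaged over the burst. This makes DBA independent
of burst length and invariant under rotations of the sensor frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AccBurst",
    "BehaviorMode",
    "MODES",
    "DEFAULT_LABEL_MAP",
    "remove_baseline",
    "compute_dba",
    "reduce_behavior",
]

#: The four behavior modes used by the energetics.
MODES = ("flap", "soar", "walk", "stationary")


@dataclass(frozen=True)
class AccBurst:
    """One burst of tri-axial acceleration.

    Parameters
    ----------
    samples
        Array of shape (n, 3): columns are surge (x), sway (y), heave (z) in g.
    sample_rate
        Samples per second; 20 Hz on the reference tags.
    """

    samples: np.ndarray
    sample_rate: float = 20.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"burst samples must have shape (n, 3), got {arr.shape}")
        if arr.shape[0] < 2:
            raise ValueError("burst needs at least 2 samples")
        if not np.all(np.isfinite(arr)):
            raise ValueError("burst contains non-finite values")
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class BehaviorMode:
    """A reduced behavior mode; ``floating`` is only meaningful when stationary."""

    mode: str
    floating: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.floating and self.mode != "stationary":
            raise ValueError("floating is only valid for stationary behavior")


#: Classifier label -> (mode, floating). Extend or override per deployment.
DEFAULT_LABEL_MAP: dict[str, tuple[str, bool]] = {
    "flap": ("flap", False),
    "flapping": ("flap", False),
    "exflap": ("flap", False),
    "soar": ("soar", False),
    "soaring": ("soar", False),
    "manouvre": ("soar", False),
    "walk": ("walk", False),
    "walking": ("walk", False),
    "sit": ("stationary", False),
    "stand": ("stationary", False),
    "stationary": ("stationary", False),
    "rest": ("stationary", False),
    "float": ("stationary", True),
    "floating": ("stationary", True),
}


def remove_baseline(burst: AccBurst) -> AccBurst:
    """Subtract the per-axis mean over the recording chunk (the burst).

    What remains is the dynamic acceleration; each axis of the result has zero
    mean to floating-point tolerance.
    """
    dynamic = burst.samples - burst.samples.mean(axis=0, keepdims=True)
    return AccBurst(dynamic, burst.sample_rate)


def compute_dba(burst: AccBurst) -> float:
    """Dynamic body acceleration of a baseline-removed burst, in g.

    DBA = mean over samples of sqrt(x² + y² + z²) of the dynamic acceleration
    (the VeDBA convention).
    """
    norms = np.linalg.norm(burst.samples, axis=1)
    return float(norms.mean())


def dba_from_raw(burst: AccBurst) -> float:
    """Convenience: baseline removal followed by DBA."""
    return compute_dba(remove_baseline(burst))


def dba_from_wide(table, prefixes: tuple[str, str, str] = ("x", "y", "z")) -> "np.ndarray":
    """DBA per row of a wide fix table with burst columns ``x_0..x_n``,
    ``y_0..y_n``, ``z_0..z_n`` (in g).

    Returns an array of one DBA value per fix (baseline removed per burst).
    """
    axes = []
    for p in prefixes:
        cols = sorted((c for c in table.columns if c.startswith(f"{p}_")),
                      key=lambda c: int(c.split("_")[-1]))
        if len(cols) < 2:
            raise ValueError(f"no burst columns found for axis {p!r}")
        axes.append(table[cols].to_numpy(dtype=float))
    stacked = np.stack(axes, axis=-1)  # (n_fixes, n_samples, 3)
    dyn = stacked - stacked.mean(axis=1, keepdims=True)
    return np.linalg.norm(dyn, axis=2).mean(axis=1)


def dba_from_long(table, fix_id: str = "fix_id",
                  axes: tuple[str, str, str] = ("x", "y", "z")):
    """DBA per burst from a long-format sample table keyed by fix id.

    Returns a pandas Series indexed by fix id, ordered by first appearance.
    """
    import pandas as pd

    def one(group):
        burst = AccBurst(group[list(axes)].to_numpy(dtype=float))
        return compute_dba(remove_baseline(burst))

    return table.groupby(fix_id, sort=False).apply(one)


def reduce_behavior(
    classifier_label: str,
    label_map: dict[str, tuple[str, bool]] | None = None,
) -> BehaviorMode:
    """Map an upstream classifier label onto one of the four behavior modes.

    Raises ``KeyError`` naming the offending label when it is not in the map.
    """
    mapping = DEFAULT_LABEL_MAP if label_map is None else label_map
    key = classifier_label.strip().lower()
    if key not in mapping:
        raise KeyError(f"unmapped behavior label: {classifier_label!r}")
    mode, floating = mapping[key]
    return BehaviorMode(mode, floating)
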