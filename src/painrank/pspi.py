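"""PSPI scoring, pain-state binning, and class balancing.

The Prkachin–Solomon Pain Intensity (PSPI) is a frame-level pain score built
from six FACS action units: AU4 (brow lower), AU6 (cheek raiser), AU7 (eyelid
tightener), AU9 (nose wrinkle), AU10 (upper lip raiser) and AU43 (eyes
closed).  The graded AUs take intensities 0-5; AU43 is binary.  The canonical
score is

    PSPI = AU4 + max(AU6, AU7) + max(AU9, AU10) + AU43

which ranges over the integers 0..16.  (Descriptions of the score as a plain
sum, with range 0-15, circulate in the literature; the plain-sum variant is
available via ``mode="sum"`` for comparison.)

Frame corpora are carried as pandas DataFrames ("manifests") with columns
``frame_path, subject_id, level, frame_index, pspi, pain_state``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AUVector",
    "PainState",
    "PainGroup",
    "PAIN_STATE_BINS",
    "compute_pspi",
    "bin_pain_state",
    "balance_by_minority",
    "read_manifest",
    "write_manifest",
    "MANIFEST_COLUMNS",
]

GRADED_AUS = ("au4", "au6", "au7", "au9", "au10")

MANIFEST_COLUMNS = ["frame_path", "subject_id", "level", "frame_index", "pspi", "pain_state"]


@dataclass(frozen=True)
class AUVector:
    """Intensities of the six PSPI action units for one frame.

    Graded AUs (au4, au6, au7, au9, au10) lie in [0, 5]; au43 is 0/1.
    """

    au4: float
    au6: float
    au7: float
    au9: float
    au10: float
    au43: int

    def __post_init__(self) -> None:
        for name in GRADED_AUS:
            v = getattr(self, name)
            if not np.isfinite(v) or not (0 <= v <= 5):
                raise ValueError(f"{name} must be finite and in [0, 5], got {v!r}")
        if self.au43 not in (0, 1):
            raise ValueError(f"au43 must be 0 or 1, got {self.au43!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.au4, self.au6, self.au7, self.au9, self.au10, self.au43], dtype=float)


class PainState(Enum):
    """Four ordered pain states binned from PSPI (none < trace < weak < strong)."""

    NONE = "none"
    TRACE = "trace"
    WEAK = "weak"
    STRONG = "strong"

    @property
    def order(self) -> int:
        return _STATE_ORDER[self]


_STATE_ORDER = {
    PainState.NONE: 0,
    PainState.TRACE: 1,
    PainState.WEAK: 2,
    PainState.STRONG: 3,
}

class PainGroup(Enum):
    """Five ordered expression groups driving the avatar (PG1 = no pain at all
    ... PG5 = very strong)."""

    PG1 = 1
    PG2 = 2
    PG3 = 3
    PG4 = 4
    PG5 = 5

    def __lt__(self, other: "PainGroup") -> bool:
        return self.value < other.value


# Closed integer PSPI intervals per state.  PSPI 16 (attainable under the
# max-pair formula) is assigned to "strong".
PAIN_STATE_BINS: dict[PainState, tuple[int, int]] = {
    PainState.NONE: (0, 0),
    PainState.TRACE: (1, 1),
    PainState.WEAK: (2, 3),
    PainState.STRONG: (4, 16),
}


def compute_pspi(au: AUVector, mode: str = "max_pair") -> int:
    """Score one frame's action units as a PSPI value in [0, 16].

    ``mode="max_pair"`` (default) uses AU4 + max(AU6,AU7) + max(AU9,AU10) +
    AU43; ``mode="sum"`` adds all six AUs.  Graded intensities are rounded to
    the nearest integer before combination so fractional AU codings still
    yield an integer score.  Monotone nondecreasing in every component.
    """
    if mode not in ("max_pair", "sum"):
        raise ValueError(f"unknown PSPI mode {mode!r}")
    au4, au6, au7, au9, au10 = (int(round(getattr(au, k))) for k in GRADED_AUS)
    if mode == "max_pair":
        return au4 + max(au6, au7) + max(au9, au10) + au.au43
    return au4 + au6 + au7 + au9 + au10 + au.au43


def bin_pain_state(pspi: int) -> PainState:
    """Map an integer PSPI score to its pain state (Table-style closed bins)."""
    if pspi < 0:
        raise ValueError(f"PSPI must be nonnegative, got {pspi}")
    for state, (lo, hi) in PAIN_STATE_BINS.items():
        if lo <= pspi <= hi:
            return state
    raise ValueError(f"PSPI {pspi} outside the supported range 0..16")


def _validate_manifest(df: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if (df["pspi"] < 0).any():
        raise ValueError("manifest contains negative PSPI values")
    states = df["pspi"].map(lambda p: bin_pain_state(int(p)).value)
    bad = df.loc[states != df["pain_state"].astype(str)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"pain_state inconsistent with pspi at frame {row['frame_path']!r}: "
            f"pspi={row['pspi']} but state={row['pain_state']!r}"
        )


def balance_by_minority(manifest: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Downsample every pain-state class to the minority class size.

    Records are drawn uniformly without replacement under ``seed``; the
    surviving rows keep their original manifest order, so within-subject frame
    ordering is preserved.  The seed is recorded in ``result.attrs`` for
    provenance.  Raises if any of the four classes is absent.
    """
    counts = manifest["pain_state"].value_counts()
    for state in PainState:
        if counts.get(state.value, 0) == 0:
            raise ValueError(f"pain-state class {state.value!r} is empty; cannot balance")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    # iterate states in fixed order so the draw sequence is reproducible
    for state in PainState:
        idx = manifest.index[manifest["pain_state"] == state.value].to_numpy()
        keep.append(rng.choice(idx, size=n_min, replace=False))
    kept = np.sort(np.concatenate(keep))
    out = manifest.loc[kept].copy()
    out.attrs["balance_seed"] = seed
    return out


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a corpus manifest CSV."""
    df = pd.read_csv(path, dtype={"frame_path": str, "subject_id": str, "pain_state": str})
    _validate_manifest(df)
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    _validate_manifest(manifest)
    manifest.to_csv(path, index=False, columns=MANIFEST_COLUMNS)
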