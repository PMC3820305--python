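"""Marker panel and cell-fate classification rules.

A seven-marker antibody panel (Nanog, Foxa2, Hex, Noggin, Tbx6, Ap-2alpha,
Sox3) is the minimal readout used to call differentiation status and
germ-layer fate of single cells from embryoid-body cultures. Two rule sets
operate on the binary marker calls:

* differentiation status is determined solely by Nanog: Nanog+ cells are
  undifferentiated, Nanog- cells have differentiated (the Foxa2/Noggin/
  Ap-2alpha cocktail may be positive or negative in either case);
* germ-layer fate is an exact pattern match of the six non-Nanog markers
  against the nine recognised differentiated signatures (mesendoderm,
  endoderm, mesoderm, ectoderm, neuroectoderm). Nanog- profiles matching no
  signature are "unclassified" — the rule table defines no nearest-fate
  fallback.

Binary calls are the input; thresholding continuous fluorescence into +/-
happens upstream.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

#: Canonical marker column order used by every event table in the package.
MARKER_COLUMNS = ("nanog", "foxa2", "hex", "noggin", "tbx6", "ap2a", "sox3")

#: All fate categories a profile can map to (a total function).
FATES = (
    "undifferentiated",
    "mesendoderm",
    "endoderm",
    "mesoderm",
    "ectoderm",
    "neuroectoderm",
    "unclassified",
)

UNDIFFERENTIATED = "undifferentiated"
DIFFERENTIATED = "differentiated"


class MarkerProfile(NamedTuple):
    """Binary (0/1) calls for one cell at one time, in panel order."""

    nanog: int
    foxa2: int
    hex: int
    noggin: int
    tbx6: int
    ap2a: int
    sox3: int


# The nine differentiated signatures, keyed by the six non-Nanog calls
# (foxa2, hex, noggin, tbx6, ap2a, sox3).
_DIFFERENTIATED_PATTERNS: dict[tuple[int, ...], str] = {
    (1, 0, 1, 0, 0, 0): "mesendoderm",   # Foxa2+ Noggin+
    (1, 0, 0, 0, 0, 0): "mesendoderm",   # Foxa2+ only
    (0, 0, 1, 0, 0, 0): "mesendoderm",   # Noggin+ only
    (1, 1, 0, 0, 0, 0): "endoderm",      # Foxa2+ Hex+
    (0, 1, 0, 0, 0, 0): "endoderm",      # Hex+ only
    (0, 0, 1, 1, 0, 0): "mesoderm",      # Noggin+ Tbx6+
    (0, 0, 0, 1, 0, 0): "mesoderm",      # Tbx6+ only
    (0, 0, 0, 0, 1, 1): "ectoderm",      # Ap-2a+ Sox3+
    (0, 0, 0, 0, 0, 1): "neuroectoderm", # Sox3+ only
}

#: Canonical (noise-free) truth profile expressed by a cell of each state.
CANONICAL_PROFILES: dict[str, MarkerProfile] = {
    "undifferentiated": MarkerProfile(1, 0, 0, 0, 0, 0, 0),
    "mesendoderm": MarkerProfile(0, 1, 0, 1, 0, 0, 0),
    "endoderm": MarkerProfile(0, 1, 1, 0, 0, 0, 0),
    "mesoderm": MarkerProfile(0, 0, 0, 1, 1, 0, 0),
    "ectoderm": MarkerProfile(0, 0, 0, 0, 0, 1, 1),
    "neuroectoderm": MarkerProfile(0, 0, 0, 0, 0, 0, 1),
}


def _coerce_profile(profile) -> MarkerProfile:
    p = MarkerProfile(*(int(v) for v in profile))
    for v in p:
        if v not in (0, 1):
            raise ValueError(f"marker calls must be binary 0/1, got {profile!r}")
    return p


def classify_differentiation(profile) -> str:
    """Call a cell 'undifferentiated' or 'differentiated'.

    The status is determined solely by the Nanog call; the antibody-cocktail
    column of the rule table is +/- in every row.
    """
    p = _coerce_profile(profile)
    return UNDIFFERENTIATED if p.nanog == 1 else DIFFERENTIATED


def classify_fate(profile) -> str:
    """Map a marker profile to its germ-layer fate (total function).

    Nanog positivity takes absolute precedence; Nanog- profiles are matched
    exactly against the nine differentiated signatures and fall through to
    "unclassified".
    """
    p = _coerce_profile(profile)
    if p.nanog == 1:
        return "undifferentiated"
    return _DIFFERENTIATED_PATTERNS.get(tuple(p[1:]), "unclassified")


# Precomputed lookup over all 2^7 profiles, indexed by the packed bit code
# sum(call_i * 2^i) in panel order.
_FATE_LUT = np.empty(128, dtype=object)
for _code in range(128):
    _bits = [(_code >> _i) & 1 for _i in range(7)]
    _FATE_LUT[_code] = classify_fate(_bits)


def classify_table(table: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_fate` over a DataFrame of marker columns."""
    missing = [c for c in MARKER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"marker columns missing: {missing}")
    code = np.zeros(len(table), dtype=np.int64)
    for i, col in enumerate(MARKER_COLUMNS):
        vals = table[col].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-binary value in column {col!r} at row {row}")
        code += vals.astype(np.int64) << i
    return pd.Series(_FATE_LUT[code], index=table.index, name="fate")


def enumerate_partition() -> dict[str, int]:
    """Count how many of the 128 possible profiles map to each category."""
    counts = {fate: 0 for fate in FATES}
    for fate in _FATE_LUT:
        counts[fate] += 1
    return counts


class FateClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based germ-layer fate classifier over binary marker profiles.

    The rules are fixed by the marker-panel definitions; ``fit`` only
    validates the input schema so the estimator composes with sklearn
    pipelines and model selection.
    """

    def fit(self, X, y=None) -> "FateClassifier":
        self._validate(X)
        self.classes_ = np.asarray(FATES)
        self.n_features_in_ = 7
        return self

    @staticmethod
    def _validate(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X[list(MARKER_COLUMNS)]
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 7:
            raise ValueError("expected an (n_cells, 7) array in panel order")
        return pd.DataFrame(X, columns=MARKER_COLUMNS)

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "classes_"):
            raise AttributeError("FateClassifier is not fitted; call fit first")
        return classify_table(self._validate(X)).to_numpy()


def profiles_iter() -> Iterable[MarkerProfile]:
    """Iterate over all 128 possible marker profiles."""
    for code in range(128):
        yield MarkerProfile(*((code >> i) & 1 for i in range(7)))
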