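"""Shared-centimorgan relationship probabilities.

A bundled calibration table gives, per relationship class, a binned relative
likelihood of observing a total shared-cM amount. Classes whose expected
sharing is empirically indistinguishable (e.g. half first cousin vs first
cousin once removed vs great-great-grandparent) carry identical likelihood
rows; :func:`default_classes` exposes one canonical representative per such
sharing group, so reported posteriors are per-group probabilities labeled by
the familiar cousin-line name.

Evidence combination across matches is a geometric mean (``P_combined``), and
``Q_factor = exp(-cv)`` rewards consistency of the per-match probabilities.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .relationship import name_relationship

__all__ = [
    "RelationshipClass",
    "CalibrationTable",
    "ProbabilityResult",
    "prob_relationship",
    "combined_probability",
    "quality_factor",
    "default_classes",
    "default_table",
    "class_label",
    "label_to_key",
]

ClassKey = tuple[int, int, bool]  # (min(g_up, g_down), max(..), half)


def class_label(g_up: int, g_down: int, half: bool) -> str:
    """Canonical label for a class key, oriented upward for direct lines."""
    lo, hi = min(g_up, g_down), max(g_up, g_down)
    if lo == hi == 0:
        raise ValueError("no (0,0) class")
    return name_relationship(hi, lo, half).label


@lru_cache(maxsize=1)
def _label_key_map() -> dict[str, ClassKey]:
    out: dict[str, ClassKey] = {}
    for a in range(0, 9):
        for b in range(a, 9):
            if a == 0 and b == 0:
                continue
            for half in (False, True):
                out.setdefault(class_label(b, a, half), (a, b, half))
    return out


def label_to_key(label: str) -> ClassKey:
    try:
        return _label_key_map()[label]
    except KeyError:
        raise KeyError(f"unknown relationship class label: {label!r}") from None


@dataclass(frozen=True)
class RelationshipClass:
    g_up: int
    g_down: int
    half: bool = False
    label: str = ""

    def __post_init__(self):
        if not self.label:
            object.__setattr__(self, "label", class_label(self.g_up, self.g_down, self.half))

    @property
    def key(self) -> ClassKey:
        return (min(self.g_up, self.g_down), max(self.g_up, self.g_down), self.half)

    @property
    def total_generations(self) -> int:
        return self.g_up + self.g_down


@dataclass
class CalibrationTable:
    """Binned per-class cM likelihoods. Classes sharing a key
    ``(min, max, half)`` share one distribution (cM sharing is symmetric)."""

    bin_edges: np.ndarray                      # len = n_bins + 1, covers [0, 3600]
    likelihood: dict[ClassKey, np.ndarray]     # key -> vector of len n_bins
    provenance: str = ""

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0) or self.bin_edges[0] < 0:
            raise ValueError("bin edges must be non-negative and increasing")
        n = len(self.bin_edges) - 1
        for key, vec in self.likelihood.items():
            vec = np.asarray(vec, dtype=float)
            if len(vec) != n:
                raise ValueError(f"class {key}: expected {n} bins, got {len(vec)}")
            if np.any(vec < 0) or not np.any(vec > 0):
                raise ValueError(f"class {key}: likelihoods must be >=0 with one positive")
            self.likelihood[key] = vec

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def max_cm(self) -> float:
        return float(self.bin_edges[-1])

    def classes(self) -> list[RelationshipClass]:
        out = []
        for (lo, hi, half) in sorted(self.likelihood):
            out.append(RelationshipClass(g_up=hi, g_down=lo, half=half))
        return out

    def evaluate(self, cls: RelationshipClass, cm: float) -> float:
        """Likelihood at a cM value: linear interpolation between bin
        midpoints, constant inside the first and last half-bins."""
        if cm < 0 or cm > self.max_cm:
            return 0.0
        vec = self.likelihood.get(cls.key)
        if vec is None:
            raise KeyError(f"class {cls.label} not in table")
        return float(np.interp(cm, self.midpoints, vec))

    def sample_cm(self, cls: RelationshipClass, rng: np.random.Generator) -> float:
        """Inverse-CDF draw from a class's binned distribution (uniform
        within the chosen bin)."""
        vec = self.likelihood[cls.key]
        widths = np.diff(self.bin_edges)
        mass = vec * widths
        mass = mass / mass.sum()
        i = int(rng.choice(len(mass), p=mass))
        return float(rng.uniform(self.bin_edges[i], self.bin_edges[i + 1]))

    # -- CSV round trip (header: class,half,bin_lo,bin_hi,likelihood) --------

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["class", "half", "bin_lo", "bin_hi", "likelihood"])
        for (lo, hi, half) in sorted(self.likelihood):
            label = class_label(hi, lo, half)
            vec = self.likelihood[(lo, hi, half)]
            for j in range(len(vec)):
                w.writerow([label, int(half),
                            f"{self.bin_edges[j]:g}", f"{self.bin_edges[j + 1]:g}",
                            f"{vec[j]:.6g}"])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str, provenance: str = "") -> "CalibrationTable":
        rows: dict[ClassKey, list[tuple[float, float, float]]] = {}
        for row in csv.DictReader(io.StringIO(text)):
            lo_key, hi_key, _ = label_to_key(row["class"])
            key = (lo_key, hi_key, bool(int(row["half"])))
            rows.setdefault(key, []).append(
                (float(row["bin_lo"]), float(row["bin_hi"]), float(row["likelihood"])))
        edges: Optional[list[float]] = None
        like: dict[ClassKey, np.ndarray] = {}
        for key, bins in rows.items():
            bins.sort()
            e = [b[0] for b in bins] + [bins[-1][1]]
            if edges is None:
                edges = e
            elif e != edges:
                raise ValueError(f"class {key}: bin edges differ from other classes")
            like[key] = np.array([b[2] for b in bins])
        if edges is None:
            raise ValueError("empty calibration table")
        return cls(bin_edges=np.array(edges), likelihood=like, provenance=provenance)


@lru_cache(maxsize=1)
def default_table() -> CalibrationTable:
    text = resources.files("kinforge.data").joinpath("shared_cm_calibration.csv").read_text()
    return CalibrationTable.from_csv(text, provenance="bundled shared-cM calibration")


# Preferred representative key per sharing group, in display order.
_REP_PREFERENCE: list[ClassKey] = [
    (0, 1, False), (1, 1, False), (1, 2, False), (2, 2, False), (2, 3, False),
    (3, 3, False), (3, 4, False), (4, 4, False), (4, 5, False), (5, 5, False),
    (6, 6, False),
]


def default_classes(table: Optional[CalibrationTable] = None) -> list[RelationshipClass]:
    """One canonical representative per distinct likelihood row."""
    table = table or default_table()
    groups: dict[bytes, list[ClassKey]] = {}
    for key, vec in table.likelihood.items():
        groups.setdefault(np.round(vec / vec.max(), 9).tobytes(), []).append(key)
    pref_rank = {k: i for i, k in enumerate(_REP_PREFERENCE)}
    reps = []
    for keys in groups.values():
        keys.sort(key=lambda k: (pref_rank.get(k, 99), k))
        lo, hi, half = keys[0]
        reps.append(RelationshipClass(g_up=hi, g_down=lo, half=half))
    reps.sort(key=lambda c: (pref_rank.get(c.key, 99), c.key))
    return reps


def equivalent_keys(cls: RelationshipClass,
                    table: Optional[CalibrationTable] = None) -> list[ClassKey]:
    """All class keys in the table sharing this class's likelihood row."""
    table = table or default_table()
    ref = table.likelihood[cls.key]
    ref = np.round(ref / ref.max(), 9)
    out = []
    for key, vec in table.likelihood.items():
        if np.array_equal(np.round(vec / vec.max(), 9), ref):
            out.append(key)
    return sorted(out)


@dataclass
class ProbabilityResult:
    posterior: dict[RelationshipClass, float]
    best: RelationshipClass

    def by_label(self) -> dict[str, float]:
        return {c.label: p for c, p in self.posterior.items()}

    def __getitem__(self, label: str) -> float:
        for c, p in self.posterior.items():
            if c.label == label:
                return p
        raise KeyError(label)


def prob_relationship(cm: float, candidates: Optional[Sequence[RelationshipClass]] = None,
                      table: Optional[CalibrationTable] = None,
                      priors: Optional[dict] = None) -> ProbabilityResult:
    """Posterior over candidate classes for one observed shared-cM amount."""
    table = table or default_table()
    if candidates is None:
        candidates = default_classes(table)
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    if cm < 0:
        raise ValueError("cM must be non-negative")

    weights = []
    for c in candidates:
        prior = 1.0 if priors is None else float(priors.get(c, priors.get(c.label, 0.0)))
        weights.append(prior * table.evaluate(c, cm))
    total = float(sum(weights))
    if total <= 0.0:
        raise ValueError(
            f"{cm} cM is outside the table's support for every candidate class")
    posterior = {c: w / total for c, w in zip(candidates, weights)}
    best = max(posterior, key=lambda c: (posterior[c], c.label))
    return ProbabilityResult(posterior=posterior, best=best)


def combined_probability(probabilities: Sequence[float]) -> float:
    """Geometric mean of per-match probabilities."""
    if len(probabilities) == 0:
        raise ValueError("need at least one probability")
    if any(p <= 0 or p > 1 for p in probabilities):
        raise ValueError("probabilities must be in (0, 1]")
    return float(math.exp(sum(math.log(p) for p in probabilities) / len(probabilities)))


def quality_factor(probabilities: Sequence[float]) -> float:
    """exp(-cv): 1.0 for perfectly consistent evidence, decaying with spread."""
    if len(probabilities) == 0:
        raise ValueError("need at least one probability")
    if any(p <= 0 or p > 1 for p in probabilities):
        raise ValueError("probabilities must be in (0, 1]")
    if len(probabilities) == 1:
        return 1.0
    arr = np.asarray(probabilities, dtype=float)
    if arr.max() == arr.min():
        return 1.0
    sd = float(arr.std(ddof=1))
    cv = sd / float(arr.mean())
    return float(math.exp(-cv))
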