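"""Biological constraint definitions: trait dependency graph, hierarchical
pairs, physiological bounds, and the local-to-global aggregation map.

A :class:`ConstraintSet` collects three kinds of domain knowledge about
plant traits:

* correlation edges — pairs of traits with a target (or threshold)
  correlation coefficient ``rho`` derived from agronomic knowledge,
  e.g. leaf number rises with main-stem height;
* hierarchical pairs — ordered inequalities in physical units,
  e.g. leaf area ≤ canopy area, root volume ≤ pot soil volume;
* bounds — per-trait physiological ranges [l_j, u_j].

The default set mirrors the expert-validated wheat rules: leaf ≤ canopy
area, root volume bounded by the soil volume, a logistic trend for dry
matter accumulation (enforced by the growth regularizer rather than a
static rule), and a positive leaf-count/height correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CorrelationEdge",
    "TraitDependencyGraph",
    "HierarchyPair",
    "AggregationMap",
    "ConstraintSet",
    "default_wheat_constraints",
]


@dataclass(frozen=True)
class CorrelationEdge:
    """An edge (trait_i, trait_j) with target correlation rho in [-1, 1].

    ``threshold`` is the hinge form's cutoff; it defaults to ``rho`` so a
    single edge definition serves both the squared-deviation penalty and
    the one-sided hinge penalty.
    """

    trait_i: str
    trait_j: str
    rho: float
    threshold: float | None = None

    def __post_init__(self):
        if self.trait_i == self.trait_j:
            raise ValueError(f"self-edge on trait {self.trait_i!r}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho={self.rho} outside [-1, 1]")

    @property
    def hinge_threshold(self) -> float:
        return self.rho if self.threshold is None else self.threshold


@dataclass
class TraitDependencyGraph:
    edges: list[CorrelationEdge] = field(default_factory=list)

    def __iter__(self):
        return iter(self.edges)

    def __len__(self):
        return len(self.edges)


@dataclass(frozen=True)
class HierarchyPair:
    """Ordered trait inequality: value of `smaller` must not exceed `larger`."""

    smaller: str
    larger: str

    def __post_init__(self):
        if self.smaller == self.larger:
            raise ValueError("hierarchy pair must relate two distinct traits")


@dataclass
class AggregationMap:
    """Linear map T from local trait vectors to global trait vectors.

    ``matrix`` has shape (d_global, d_local); ``x_global = T @ x_local``.
    """

    matrix: np.ndarray
    local_names: list[str]
    global_names: list[str]
    learnable: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (len(self.global_names), len(self.local_names)):
            raise ValueError(
                f"aggregation matrix shape {self.matrix.shape} does not match "
                f"({len(self.global_names)}, {len(self.local_names)})"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("aggregation matrix must be finite")

    def apply(self, local: np.ndarray) -> np.ndarray:
        """Apply to one local trait vector or a stack of them (last axis)."""
        return np.asarray(local) @ self.matrix.T


@dataclass
class ConstraintSet:
    graph: TraitDependencyGraph = field(default_factory=TraitDependencyGraph)
    hierarchy_pairs: list[HierarchyPair] = field(default_factory=list)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    growth_trend: str = "logistic"

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if lo >= hi:
                raise ValueError(f"bound for {name!r}: lower {lo} >= upper {hi}")

    # JSON round-trip -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "correlation_edges": [
                {
                    "trait_i": e.trait_i,
                    "trait_j": e.trait_j,
                    "rho": e.rho,
                    "threshold": e.threshold,
                }
                for e in self.graph
            ],
            "hierarchy_pairs": [
                {"smaller": p.smaller, "larger": p.larger} for p in self.hierarchy_pairs
            ],
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "growth_trend": self.growth_trend,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConstraintSet":
        return cls(
            graph=TraitDependencyGraph(
                [
                    CorrelationEdge(
                        e["trait_i"], e["trait_j"], e["rho"], e.get("threshold")
                    )
                    for e in d.get("correlation_edges", [])
                ]
            ),
            hierarchy_pairs=[
                HierarchyPair(p["smaller"], p["larger"])
                for p in d.get("hierarchy_pairs", [])
            ],
            bounds={k: (float(v[0]), float(v[1])) for k, v in d.get("bounds", {}).items()},
            growth_trend=d.get("growth_trend", "logistic"),
        )

    def save(self, path: str | Path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ConstraintSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_wheat_constraints() -> ConstraintSet:
    """Expert-style wheat rule set.

    R1: leaf area ≤ canopy area (hierarchy); R2: root volume within the pot
    soil volume (upper bound); R3: logistic growth trend (handled by the
    growth regularizer); R5: leaf count positively correlated with plant
    height (target rho 0.8, hinge threshold 0.95).
    """
    return ConstraintSet(
        graph=TraitDependencyGraph(
            [CorrelationEdge("leaf_count", "plant_height", rho=0.8, threshold=0.95)]
        ),
        hierarchy_pairs=[HierarchyPair("leaf_area", "canopy_area")],
        bounds={
            "leaf_area": (0.0, 300.0),      # cm^2
            "plant_height": (0.0, 150.0),   # cm
            "leaf_count": (0.0, 25.0),      # count
            "root_volume": (0.0, 3000.0),   # cm^3, pot soil volume cap
            "canopy_area": (0.0, 600.0),    # cm^2
            "shoot_biomass": (0.0, 60.0),   # g
        },
        growth_trend="logistic",
    )
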