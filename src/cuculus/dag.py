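"""Directed acyclic graph describing the timing model.

The six migratory milestones are endogenous nodes; bird- or year-level
covariates (breeding habitat, post-breeding route, breeding coordinates,
pre-Sahara stopover locations) are exogenous.  The same ``DagSpec`` doubles
as (a) the generating model of the synthetic-data module, where every edge
carries a true standardized coefficient, and (b) the declared structure
handed to the Bayesian path-analysis fitter, where coefficients are
estimated.

All variables live on the standardized (unit-variance) scale: each
endogenous node's residual variance is derived so that its marginal
variance is exactly 1, which makes the structural coefficients equal to
standardized path coefficients and keeps the squaring rule for variance
shares exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import yaml
from scipy.optimize import brentq

#: Milestone kinds in annual-cycle order.
MILESTONES = [
    "depart_breeding",        # M1
    "complete_sahara_south",  # M2
    "arrive_winter",          # M3
    "depart_winter",          # M4
    "depart_west_africa",     # M5
    "arrive_breeding",        # M6
]


class CyclicDagError(ValueError):
    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("graph contains a cycle: " + " -> ".join(map(str, self.cycle)))


@dataclass
class ExoVar:
    """Exogenous covariate: binary or continuous, bird- or year-level."""

    kind: str = "continuous"   # "continuous" | "binary"
    level: str = "bird"        # "bird" | "year"
    p: float = 0.5             # success probability for binary variables

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"bad exogenous kind {self.kind!r}")
        if self.level not in ("bird", "year"):
            raise ValueError(f"bad exogenous level {self.level!r}")
        if not 0.0 < self.p < 1.0:
            raise ValueError("binary probability must lie in (0,1)")


@dataclass
class DagSpec:
    """Node set, directed edges with (true) standardized coefficients, and
    the per-node split of residual variance into between- and within-
    individual parts."""

    endogenous: list[str] = field(default_factory=lambda: list(MILESTONES))
    exogenous: dict[str, ExoVar] = field(default_factory=dict)
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    between_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        nodes = set(self.endogenous) | set(self.exogenous)
        for (a, b) in self.edges:
            if a not in nodes or b not in nodes:
                raise ValueError(f"edge ({a!r}, {b!r}) has an undeclared endpoint")
            if b in self.exogenous:
                raise ValueError(f"edge into exogenous node {b!r}")
        g = self.to_networkx()
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise CyclicDagError([e[0] for e in cycle] + [cycle[-1][1]])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.endogenous)
        g.add_nodes_from(self.exogenous)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> list[str]:
        return sorted([a for (a, b) in self.edges if b == node],
                      key=self._node_order)

    def children(self, node: str) -> list[str]:
        return sorted([b for (a, b) in self.edges if a == node],
                      key=self._node_order)

    def topological_endogenous(self) -> list[str]:
        order = [n for n in nx.topological_sort(self.to_networkx())
                 if n in self.endogenous]
        return order

    def all_nodes(self) -> list[str]:
        return list(self.exogenous) + list(self.endogenous)

    def _node_order(self, n: str) -> tuple[int, int | str]:
        allnodes = self.all_nodes()
        return (0, allnodes.index(n)) if n in allnodes else (1, n)

    def coefficient(self, a: str, b: str) -> float:
        return float(self.edges.get((a, b), 0.0))

    # -- implied moments ---------------------------------------------------
    def implied_components(self) -> dict[str, dict[str, float]]:
        """Analytic between/within variance decomposition per node.

        Propagates two covariance matrices through the linear-Gaussian
        system in topological order: bird-level variance (bird-level
        exogenous variables plus individual random intercepts) and
        year-level variance (year-level exogenous variables plus residual
        noise).  Each endogenous node's residual variance is whatever is
        left after its parents, so totals are exactly 1.
        """
        nodes = self.all_nodes()
        idx = {n: i for i, n in enumerate(nodes)}
        p = len(nodes)
        sig_b = np.zeros((p, p))
        sig_w = np.zeros((p, p))
        for name, exo in self.exogenous.items():
            (sig_b if exo.level == "bird" else sig_w)[idx[name], idx[name]] = 1.0
        out: dict[str, dict[str, float]] = {}
        for node in self.topological_endogenous():
            k = idx[node]
            pars = self.parents(node)
            a = np.array([self.coefficient(pp, node) for pp in pars])
            ji = [idx[pp] for pp in pars]
            tot = sig_b + sig_w
            v_explained = float(a @ tot[np.ix_(ji, ji)] @ a) if pars else 0.0
            resid = 1.0 - v_explained
            if resid <= 1e-10:
                raise ValueError(
                    f"node {node!r}: explained variance {v_explained:.3f} >= 1; "
                    "edge coefficients too large for a standardized system")
            f = float(self.between_fraction.get(node, 0.0))
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"between_fraction[{node!r}] outside [0,1]")
            # covariances with every already-defined node
            for m in range(p):
                cb = float(a @ sig_b[ji, m]) if pars else 0.0
                cw = float(a @ sig_w[ji, m]) if pars else 0.0
                sig_b[k, m] = sig_b[m, k] = cb
                sig_w[k, m] = sig_w[m, k] = cw
            vb = (float(a @ sig_b[np.ix_(ji, ji)] @ a) if pars else 0.0) + f * resid
            vw = (float(a @ sig_w[np.ix_(ji, ji)] @ a) if pars else 0.0) + (1 - f) * resid
            sig_b[k, k] = vb
            sig_w[k, k] = vw
            out[node] = {
                "explained": v_explained,
                "residual": resid,
                "sigma2_between_resid": f * resid,
                "sigma2_within_resid": (1 - f) * resid,
                "between": vb,
                "within": vw,
                "repeatability": vb / (vb + vw),
            }
        return out

    def residual_sds(self) -> dict[str, tuple[float, float]]:
        """(between, within) residual SDs per endogenous node."""
        comp = self.implied_components()
        return {n: (np.sqrt(c["sigma2_between_resid"]),
                    np.sqrt(c["sigma2_within_resid"])) for n, c in comp.items()}

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "endogenous": list(self.endogenous),
            "exogenous": {n: {"kind": e.kind, "level": e.level, "p": e.p}
                          for n, e in self.exogenous.items()},
            "edges": [{"from": a, "to": b, "coefficient": c}
                      for (a, b), c in self.edges.items()],
            "between_fraction": dict(self.between_fraction),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DagSpec":
        return cls(
            endogenous=list(d["endogenous"]),
            exogenous={n: ExoVar(**v) for n, v in d.get("exogenous", {}).items()},
            edges={(e["from"], e["to"]): float(e.get("coefficient", 0.0))
                   for e in d.get("edges", [])},
            between_fraction={k: float(v)
                              for k, v in d.get("between_fraction", {}).items()},
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DagSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_timing_dag() -> DagSpec:
    """The declared timing-model structure with the generator's true
    standardized coefficients.

    Structure: habitat and route feed every milestone; breeding coordinates
    feed departure from and arrival at the breeding grounds; the last
    European pre-Sahara stopover latitude feeds the southbound Sahara
    crossing; the last West African stopover longitude feeds departure from
    West Africa; every milestone feeds the next one and breeding-grounds
    arrival; and a direct southbound-crossing -> West-Africa-departure edge
    (the d-separation-guided revision) replaces a winter-arrival ->
    West-Africa-departure link.

    True coefficients echo the magnitudes reported for this system: the
    0.883 West-Africa-departure effect on arrival, the 0.516 (=sqrt 0.266)
    carry-over from the southbound crossing, the 0.397 (=sqrt 0.158) effect
    of breeding departure on the crossing, stopover-location effects of
    -0.224 (sqrt 0.05) and 0.274 (sqrt 0.075), a -0.329 (sqrt 0.108)
    winter-departure effect on arrival and a 0.653 (sqrt 0.426) breeding-
    longitude effect on breeding departure.
    """
    M1, M2, M3, M4, M5, M6 = MILESTONES
    exogenous = {
        "habitat": ExoVar(kind="binary", level="bird", p=0.5),
        "route": ExoVar(kind="binary", level="bird", p=0.5),
        "breeding_lat": ExoVar(kind="continuous", level="bird"),
        "breeding_lon": ExoVar(kind="continuous", level="bird"),
        "eu_stopover_lat": ExoVar(kind="continuous", level="year"),
        "wa_stopover_lon": ExoVar(kind="continuous", level="year"),
    }
    edges: dict[tuple[str, str], float] = {}
    habitat_eff = {M1: 0.05, M2: -0.12, M3: 0.05, M4: -0.15, M5: 0.05, M6: 0.03}
    route_eff = {M1: 0.05, M2: 0.08, M3: 0.05, M4: 0.15, M5: 0.05, M6: 0.03}
    for m in MILESTONES:
        edges[("habitat", m)] = habitat_eff[m]
        edges[("route", m)] = route_eff[m]
    edges[("breeding_lon", M1)] = 0.653
    edges[("breeding_lat", M1)] = 0.10
    edges[("breeding_lon", M6)] = 0.05
    edges[("breeding_lat", M6)] = 0.05
    edges[("eu_stopover_lat", M2)] = -0.224
    edges[("wa_stopover_lon", M5)] = 0.274
    # chain + direct-to-arrival links
    edges[(M1, M2)] = 0.397
    edges[(M2, M3)] = 0.30
    edges[(M3, M4)] = 0.25
    edges[(M4, M5)] = 0.15
    edges[(M5, M6)] = 0.883
    edges[(M1, M6)] = -0.05
    edges[(M2, M6)] = 0.05
    edges[(M3, M6)] = 0.05
    edges[(M4, M6)] = -0.329
    edges[(M2, M5)] = 0.516  # d-sep-guided direct carry-over
    between = {m: 0.45 for m in MILESTONES}
    return DagSpec(exogenous=exogenous, edges=edges, between_fraction=between)


def null_dag() -> DagSpec:
    """All edge coefficients zero, no individual variance: i.i.d. timing."""
    dag = default_timing_dag()
    dag.edges = {e: 0.0 for e in dag.edges}
    dag.between_fraction = {m: 0.0 for m in MILESTONES}
    return dag


def calibrate_between_fraction(dag: DagSpec, node: str, target_r: float) -> float:
    """Choose a common between-individual residual fraction so that the
    implied marginal repeatability of ``node`` equals ``target_r``.

    Bird-level exogenous covariates already contribute between-individual
    variance, so the required residual fraction is solved numerically.
    """
    if node not in dag.endogenous:
        raise ValueError(f"{node!r} is not an endogenous node")

    def r_at(f: float) -> float:
        dag.between_fraction = {m: f for m in dag.endogenous}
        return dag.implied_components()[node]["repeatability"] - target_r

    lo, hi = 1e-6, 1 - 1e-6
    if r_at(lo) > 0:
        raise ValueError(f"target repeatability {target_r} below the floor set "
                         "by bird-level covariates")
    f = brentq(r_at, lo, hi, xtol=1e-8)
    dag.between_fraction = {m: float(f) for m in dag.endogenous}
    return float(f)
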