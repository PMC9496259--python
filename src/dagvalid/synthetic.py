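"""Linear-Gaussian structural-equation simulation from a signed DAG.

Each non-root node is a linear combination of its parents plus independent
Gaussian noise; root nodes with the exposure role follow a configurable
design — either standard-normal, or the unloading-group design used in
hind-limb partial-weightbearing rodent studies (groups at 0 %, 60 % and 80 %
unloading), or binary flight-vs-control.  Path-coefficient signs must match
the DAG's edge signs, so the simulated data are faithful to the DAG's
implied marginal directions at sufficient sample size.

The module also computes the covariance matrix implied analytically by the
path coefficients, which allows population-level (exact, non-sampled) checks
that every implied conditional independence has partial correlation zero.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dag import CausalDAG, DagError, parse_dag, topological_order
from .implications import IndependenceStatement
from .stats import partial_correlation

__all__ = [
    "GroupedExposure",
    "SemSpec",
    "SyntheticStudy",
    "simulate_sem",
    "implied_covariance",
    "population_partial_correlation",
    "perturb_spec",
    "make_study_suite",
    "bone_dag",
    "bone_sem_spec",
    "BONE_DAG_TEXT",
]

# Six-variable bone-remodelling diagram: skeletal unloading suppresses bone
# formation and stimulates bone resorption; both processes determine bone mass
# and trabecular microarchitecture, which jointly determine bone strength.
BONE_DAG_TEXT = """\
unloading [exposure]
strength [outcome]
unloading -> formation [sign=-]
unloading -> resorption [sign=+]
formation -> mass [sign=+]
formation -> trabecular [sign=+]
resorption -> mass [sign=-]
resorption -> trabecular [sign=-]
mass -> strength [sign=+]
trabecular -> strength [sign=+]
"""


def bone_dag() -> CausalDAG:
    """The six-node skeletal-unloading → bone-strength diagram."""
    return parse_dag(BONE_DAG_TEXT)


@dataclass(frozen=True)
class GroupedExposure:
    """Exposure drawn from discrete design groups (e.g. degree of unloading)."""

    values: tuple[float, ...] = (0.0, 0.60, 0.80)
    sizes: Optional[tuple[int, ...]] = None  # None -> near-equal split

    def assign(self, n: int, rng: np.random.Generator) -> np.ndarray:
        sizes = self.sizes
        if sizes is None:
            base, extra = divmod(n, len(self.values))
            sizes = tuple(base + (1 if i < extra else 0) for i in range(len(self.values)))
        if sum(sizes) != n:
            raise ValueError(f"group sizes {sizes} do not sum to n={n}")
        out = np.repeat(self.values, sizes).astype(float)
        return rng.permutation(out)

    def variance(self, n: int) -> float:
        sizes = self.sizes
        if sizes is None:
            base, extra = divmod(n, len(self.values))
            sizes = tuple(base + (1 if i < extra else 0) for i in range(len(self.values)))
        w = np.asarray(sizes, float) / sum(sizes)
        v = np.asarray(self.values, float)
        mu = float(w @ v)
        return float(w @ (v - mu) ** 2)


ExposureDesign = Union[Literal["continuous_gaussian"], GroupedExposure]


@dataclass
class SemSpec:
    """A signed DAG with concrete path coefficients and noise scales."""

    dag: CausalDAG
    coefficients: dict[tuple[str, str], float]
    noise_sd: dict[str, float] = field(default_factory=dict)
    exposure_design: ExposureDesign = "continuous_gaussian"
    n: int = 100
    seed: int = 0
    perturbations: tuple[str, ...] = ()

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        for edge in self.coefficients:
            if edge not in self.dag.edges:
                raise DagError(f"coefficient for non-edge {edge!r}")
        for edge, sign in self.dag.edges.items():
            beta = self.coefficients.get(edge, 0.0)
            if sign is not None and beta != 0 and np.sign(beta) != sign:
                raise DagError(
                    f"coefficient {beta} contradicts the sign of edge {edge!r}"
                )
        for node in self.dag.nodes:
            if not self._is_designed_exposure(node):
                sd = self.noise_sd.get(node, 1.0)
                if sd <= 0:
                    raise ValueError(f"noise_sd for {node!r} must be > 0")

    def _is_designed_exposure(self, node: str) -> bool:
        return (
            self.dag.roles.get(node) == "exposure"
            and not self.dag.parents(node)
            and isinstance(self.exposure_design, GroupedExposure)
        )

    def node_variance(self, node: str) -> float:
        """Exogenous variance contributed at this node (design or noise)."""
        if self._is_designed_exposure(node):
            return self.exposure_design.variance(self.n)
        return self.noise_sd.get(node, 1.0) ** 2

    def to_dict(self) -> dict:
        return {
            "nodes": {n: self.dag.roles[n] for n in self.dag.nodes},
            "edges": [
                {
                    "source": s,
                    "target": t,
                    "sign": self.dag.edges[(s, t)],
                    "coefficient": self.coefficients.get((s, t), 0.0),
                }
                for (s, t) in sorted(self.dag.edges)
            ],
            "noise_sd": {n: self.noise_sd.get(n, 1.0) for n in self.dag.nodes},
            "exposure_design": (
                "continuous_gaussian"
                if self.exposure_design == "continuous_gaussian"
                else {
                    "values": list(self.exposure_design.values),
                    "sizes": list(self.exposure_design.sizes)
                    if self.exposure_design.sizes
                    else None,
                }
            ),
            "n": self.n,
            "seed": self.seed,
            "perturbations": list(self.perturbations),
        }


@dataclass
class SyntheticStudy:
    data: pd.DataFrame
    truth: SemSpec
    measured_subset: tuple[str, ...]
    missingness: dict[str, float] = field(default_factory=dict)
    label: str = "study"

    def write(self, prefix: str) -> tuple[str, str]:
        """Write `<prefix>.csv` and a `<prefix>.truth.json` sidecar."""
        csv_path, truth_path = f"{prefix}.csv", f"{prefix}.truth.json"
        self.data.to_csv(csv_path, index=False)
        sidecar = {
            "label": self.label,
            "measured_subset": list(self.measured_subset),
            "missingness": self.missingness,
            "sem": self.truth.to_dict(),
        }
        with open(truth_path, "w") as fh:
            json.dump(sidecar, fh, indent=2)
        return csv_path, truth_path


def simulate_sem(spec: SemSpec) -> SyntheticStudy:
    """Draw a dataset from the structural equations, in topological order."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    order = topological_order(spec.dag)
    columns: dict[str, np.ndarray] = {}
    for node in order:
        parents = spec.dag.parents(node)
        if spec._is_designed_exposure(node):
            columns[node] = spec.exposure_design.assign(spec.n, rng)
            continue
        value = rng.normal(0.0, spec.noise_sd.get(node, 1.0), size=spec.n)
        for p in parents:
            value += spec.coefficients.get((p, node), 0.0) * columns[p]
        columns[node] = value
    data = pd.DataFrame({n: columns[n] for n in sorted(order)})
    return SyntheticStudy(
        data=data,
        truth=spec,
        measured_subset=tuple(sorted(order)),
        missingness={n: 0.0 for n in order},
    )


def implied_covariance(spec: SemSpec) -> pd.DataFrame:
    """Population covariance implied by the path coefficients.

    With x = B^T x + e and exogenous covariance Omega (diagonal), the implied
    covariance is (I - B^T)^{-1} Omega (I - B^T)^{-T}.
    """
    nodes = spec.dag.nodes
    index = {n: i for i, n in enumerate(nodes)}
    p = len(nodes)
    B = np.zeros((p, p))
    for (s, t), beta in spec.coefficients.items():
        B[index[s], index[t]] = beta
    omega = np.diag([spec.node_variance(n) for n in nodes])
    inv = np.linalg.inv(np.eye(p) - B.T)
    sigma = inv @ omega @ inv.T
    return pd.DataFrame(sigma, index=nodes, columns=nodes)


def population_partial_correlation(
    spec: SemSpec, x: str, y: str, z: Sequence[str] = ()
) -> float:
    """Exact partial correlation under the SEM (no sampling involved)."""
    sigma = implied_covariance(spec)
    sd = np.sqrt(np.diag(sigma.to_numpy()))
    corr = sigma / np.outer(sd, sd)
    return partial_correlation(corr, x, y, z)


def population_check_independencies(
    spec: SemSpec, statements: Sequence[IndependenceStatement]
) -> dict[IndependenceStatement, float]:
    """Population partial correlation for each statement (should be ~0)."""
    return {
        s: population_partial_correlation(spec, s.x, s.y, sorted(s.conditioning_set))
        for s in statements
    }


# -- perturbations -------------------------------------------------------------

def perturb_spec(spec: SemSpec, perturbation: tuple) -> SemSpec:
    """Return a misspecified copy of the SEM; the truth records the change.

    Perturbations:
      ("flip_edge_sign", (src, tgt))          negate a coefficient (and edge sign)
      ("add_edge", (src, tgt), coefficient)   insert a new direct effect
      ("zero_edge", (src, tgt))               remove an effect, keep the edge absent
    """
    kind = perturbation[0]
    dag = CausalDAG(roles=dict(spec.dag.roles), edges=dict(spec.dag.edges))
    coefficients = dict(spec.coefficients)
    if kind == "flip_edge_sign":
        edge = tuple(perturbation[1])
        if edge not in dag.edges:
            raise DagError(f"no edge {edge!r} to flip")
        if dag.edges[edge] is not None:
            dag.edges[edge] = -dag.edges[edge]
        coefficients[edge] = -coefficients.get(edge, 0.0)
        tag = f"flip_edge_sign:{edge[0]}->{edge[1]}"
    elif kind == "add_edge":
        edge = tuple(perturbation[1])
        beta = float(perturbation[2])
        if edge in dag.edges or (edge[1], edge[0]) in dag.edges:
            raise DagError(f"edge {edge!r} already present")
        dag.edges[edge] = int(np.sign(beta)) if beta else None
        dag.validate()  # raises on a created cycle
        coefficients[edge] = beta
        tag = f"add_edge:{edge[0]}->{edge[1]}:{beta}"
    elif kind == "zero_edge":
        edge = tuple(perturbation[1])
        if edge not in dag.edges:
            raise DagError(f"no edge {edge!r} to zero")
        del dag.edges[edge]
        coefficients.pop(edge, None)
        tag = f"zero_edge:{edge[0]}->{edge[1]}"
    else:
        raise ValueError(f"unknown perturbation {kind!r}")
    return SemSpec(
        dag=dag,
        coefficients=coefficients,
        noise_sd=dict(spec.noise_sd),
        exposure_design=spec.exposure_design,
        n=spec.n,
        seed=spec.seed,
        perturbations=spec.perturbations + (tag,),
    )


# -- study emulation -----------------------------------------------------------

def bone_sem_spec(
    n: int = 33,
    seed: int = 0,
    beta: float = 0.5,
    exposure_design: ExposureDesign = GroupedExposure(),
) -> SemSpec:
    """Faithful SEM over the bone DAG: |coefficient| = beta, signs per the DAG."""
    dag = bone_dag()
    coefficients = {edge: sign * beta for edge, sign in dag.edges.items()}
    return SemSpec(
        dag=dag,
        coefficients=coefficients,
        noise_sd={node: 1.0 for node in dag.nodes},
        exposure_design=exposure_design,
        n=n,
        seed=seed,
    )


STUDY_TEMPLATES = ("full", "formation_resorption_subset", "mass_architecture_subset")

_SUBSET_NODES = {
    # spaceflight vertebra studies: turnover markers plus mass, no strength test
    "formation_resorption_subset": ("unloading", "formation", "resorption", "mass"),
    # spaceflight studies assaying mass, microarchitecture and strength
    "mass_architecture_subset": ("unloading", "mass", "trabecular", "strength"),
}


def make_study_suite(
    dag: CausalDAG,
    template: str = "full",
    n: int = 33,
    seed: int = 0,
    beta: float = 0.5,
    subcohort: int = 14,
) -> list[SyntheticStudy]:
    """Generate studies mimicking the rodent designs' partial assay coverage.

    ``full`` emulates the partial-weightbearing design: all nodes measured at
    sample size ``n`` with the grouped 0/60/80 % exposure, but bone-turnover
    assays (formation, resorption) only available on a sub-cohort, so
    conditional tests involving them run at the smaller effective n.  The
    subset templates emulate spaceflight designs with binary flight-vs-control
    exposure and a reduced assay panel; they are defined for the bone DAG's
    node names.
    """
    if template not in STUDY_TEMPLATES:
        raise ValueError(f"unknown template {template!r}; choose from {STUDY_TEMPLATES}")
    if template == "full":
        spec = SemSpec(
            dag=dag,
            coefficients={e: (s or 1) * beta for e, s in dag.edges.items()},
            noise_sd={node: 1.0 for node in dag.nodes},
            exposure_design=GroupedExposure(),
            n=n,
            seed=seed,
        )
        study = simulate_sem(spec)
        turnover = [c for c in ("formation", "resorption") if c in study.data.columns]
        if turnover and 0 < subcohort < n:
            study.data.loc[subcohort:, turnover] = np.nan
            for c in turnover:
                study.missingness[c] = 1 - subcohort / n
        study.label = f"{template}_n{n}"
        return [study]

    nodes = _SUBSET_NODES[template]
    missing = [c for c in nodes if c not in dag.roles]
    if missing:
        raise DagError(f"template {template!r} needs nodes {missing} absent from the DAG")
    spec = SemSpec(
        dag=dag,
        coefficients={e: (s or 1) * beta for e, s in dag.edges.items()},
        noise_sd={node: 1.0 for node in dag.nodes},
        exposure_design=GroupedExposure(values=(0.0, 1.0)),  # flight vs control
        n=n,
        seed=seed,
    )
    study = simulate_sem(spec)
    study.data = study.data.loc[:, list(sorted(nodes))]
    study.measured_subset = tuple(sorted(nodes))
    study.missingness = {c: 0.0 for c in nodes}
    study.label = f"{template}_n{n}"
    return [study]
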