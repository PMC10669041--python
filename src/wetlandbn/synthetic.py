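"""Synthetic wetland-trait tables with a known copula dependence structure.

The generator emulates the survey data the analysis expects: a small
site-by-trait table whose columns have the declared ranges and ordinal
scales, and whose dependence follows a chosen z-space correlation matrix
realized through a Gaussian copula.  Continuous traits use uniform or
log-uniform shapes over their range, ordinal traits threshold the copula
uniform at interior cut-points, and count traits round a scaled uniform
into their integer range.  Because the generating matrix is recorded,
parameter-recovery experiments can compare fitted arc partials against
the ground truth.

The default specification mirrors the study system: nine drivers and a
species-richness target over 22 wetlands, with salinity, tourism
pressure, discharges, anthropization, water level and isolation
correlating negatively — and water diversions and wetland size
positively — with richness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .copula import GaussianCopulaModel, is_positive_definite, sample_gaussian_copula
from .errors import ValidationError
from .network import NetworkStructure, default_structure, extract_arc_partials, fit
from .traits import TARGET, TraitSchema, WetlandTable, default_schema

__all__ = ["MarginSpec", "SyntheticSpec", "default_spec", "generate", "recovery_experiment"]


@dataclass(frozen=True)
class MarginSpec:
    """How one column maps copula uniforms to the data scale.

    kind ``"continuous"``: linear (``shape="uniform"``) or logarithmic
    (``shape="loguniform"``) stretch of u over [low, high].
    kind ``"ordinal"``: levels low..high, assigned by thresholding u at
    the strictly increasing interior ``cutpoints`` in (0, 1).
    kind ``"count"``: u scaled over the integer range and rounded.
    """

    kind: str
    low: float
    high: float
    shape: str = "uniform"
    cutpoints: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal", "count"):
            raise ValidationError(f"unknown margin kind {self.kind!r}")
        if self.low > self.high:
            raise ValidationError("margin low > high")
        if self.kind == "ordinal":
            n_levels = int(self.high - self.low) + 1
            cps = self.cutpoints
            if len(cps) != n_levels - 1:
                raise ValidationError(
                    f"ordinal margin needs {n_levels - 1} cutpoints, got {len(cps)}"
                )
            if any(not 0 < c < 1 for c in cps) or any(
                b <= a for a, b in zip(cps, cps[1:])
            ):
                raise ValidationError("cutpoints must be strictly increasing in (0,1)")
        if self.kind == "continuous" and self.shape == "loguniform" and self.low <= 0:
            raise ValidationError("loguniform margin needs a positive lower bound")

    def transform(self, u: np.ndarray) -> np.ndarray:
        if self.kind == "continuous":
            if self.shape == "loguniform":
                return np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low)))
            return self.low + u * (self.high - self.low)
        if self.kind == "ordinal":
            return self.low + np.searchsorted(np.asarray(self.cutpoints), u)
        # count: equal mass per integer level
        n_levels = int(self.high - self.low) + 1
        return self.low + np.minimum(np.floor(u * n_levels), n_levels - 1)


@dataclass
class SyntheticSpec:
    """Ground-truth specification for a synthetic wetland table."""

    n_wetlands: int
    true_R: pd.DataFrame
    margin_specs: dict[str, MarginSpec]
    seed: int = 0
    schema: list[TraitSchema] = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        names = list(self.true_R.columns)
        if names != list(self.true_R.index):
            raise ValidationError("true_R index and columns must match")
        R = self.true_R.to_numpy(dtype=float)
        if not np.allclose(R, R.T, atol=1e-10) or not np.allclose(np.diag(R), 1.0):
            raise ValidationError("true_R must be symmetric with unit diagonal")
        if not is_positive_definite(R, 1e-10):
            raise ValidationError("true_R must be positive definite")
        if set(names) != set(self.margin_specs):
            raise ValidationError("margin_specs must cover exactly the true_R nodes")
        by_name = {s.name: s for s in self.schema}
        for name, m in self.margin_specs.items():
            if name in by_name:
                lo, hi = by_name[name].allowed_range
                if m.low < lo or m.high > hi:
                    raise ValidationError(
                        f"margin range for {name!r} exceeds schema range [{lo}, {hi}]"
                    )

    @property
    def node_names(self) -> list[str]:
        return list(self.true_R.columns)


#: z-space correlations of each driver with species richness in the
#: default spec.  Signs follow the conceptual model (pressures and high
#: water hurt richness; diversions and size favour it); joint magnitudes
#: are capped so that the arrow-shaped matrix stays positive definite.
DEFAULT_TARGET_CORR = {
    "wetland size": 0.40,
    "isolation": -0.25,
    "distance to coastline": -0.20,
    "mean water level": -0.30,
    "water salinity": -0.45,
    "water diversions": 0.30,
    "water discharges": -0.32,
    "tourism pressure": -0.38,
    "anthropization": -0.25,
}

#: inter-driver dependence: diversions drain water, lowering the level
DEFAULT_DRIVER_CORR = {("water diversions", "mean water level"): -0.30}


def default_spec(n_wetlands: int = 22, seed: int = 0) -> SyntheticSpec:
    """Ten-node specification emulating the surveyed wetland system."""
    schema = default_schema()
    names = [s.name for s in schema]
    R = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for driver, rho in DEFAULT_TARGET_CORR.items():
        R.loc[driver, TARGET] = R.loc[TARGET, driver] = rho
    for (a, b), rho in DEFAULT_DRIVER_CORR.items():
        R.loc[a, b] = R.loc[b, a] = rho
    margins = {
        "wetland size": MarginSpec("continuous", 13.3, 2048.0, "loguniform"),
        "isolation": MarginSpec("continuous", 296.0, 54472.0, "loguniform"),
        "distance to coastline": MarginSpec("continuous", 0.0, 2050.0),
        "mean water level": MarginSpec("count", 1, 11),
        "water salinity": MarginSpec("ordinal", 0, 3, cutpoints=(0.40, 0.65, 0.82)),
        "water diversions": MarginSpec("ordinal", 0, 3, cutpoints=(0.35, 0.60, 0.82)),
        "water discharges": MarginSpec("ordinal", 0, 2, cutpoints=(0.50, 0.80)),
        "tourism pressure": MarginSpec("ordinal", 0, 3, cutpoints=(0.30, 0.55, 0.80)),
        "anthropization": MarginSpec("ordinal", 0, 2, cutpoints=(0.45, 0.80)),
        TARGET: MarginSpec("count", 2, 32),
    }
    return SyntheticSpec(n_wetlands, R, margins, seed=seed, schema=schema)


def generate(spec: SyntheticSpec, seed: int | None = None) -> WetlandTable:
    """Draw a schema-valid wetland table from the specification.

    Reproducible: the same spec (including its seed) yields the same
    table; pass ``seed`` to override the spec's stored seed.
    """
    use_seed = spec.seed if seed is None else seed
    model = GaussianCopulaModel(tuple(spec.node_names), spec.true_R.to_numpy(dtype=float))
    u = sample_gaussian_copula(model, spec.n_wetlands, use_seed)
    cols = {}
    for j, name in enumerate(spec.node_names):
        cols[name] = spec.margin_specs[name].transform(u[:, j])
    width = max(2, len(str(spec.n_wetlands)))
    frame = pd.DataFrame(cols)
    frame.index = pd.Index(
        [f"w{i + 1:0{width}d}" for i in range(spec.n_wetlands)], name="wetland_id"
    )
    return WetlandTable(frame, table_schema(spec))


def table_schema(spec: SyntheticSpec) -> list[TraitSchema]:
    """Schema covering exactly the spec's nodes.

    Nodes known to the spec's reference schema keep their declared entry;
    any other node gets an entry inferred from its margin."""
    by_name = {s.name: s for s in spec.schema}
    out = []
    for name in spec.node_names:
        if name in by_name:
            out.append(by_name[name])
        else:
            m = spec.margin_specs[name]
            out.append(TraitSchema(name, m.kind, "", (m.low, m.high)))
    return out


def true_arc_partials(
    spec: SyntheticSpec, structure: NetworkStructure
) -> dict[tuple[str, str], float]:
    """Ground-truth arc partials: partial correlations of ``true_R``."""
    return extract_arc_partials(spec.true_R, structure)


def recovery_experiment(
    spec: SyntheticSpec,
    n_rows: int,
    seed: int = 0,
    structure: NetworkStructure | None = None,
) -> pd.DataFrame:
    """Generate -> fit -> compare arc partials against the ground truth.

    Returns one row per arc with the true partial (from ``true_R``), the
    fitted partial (bn_constrained fit of a table of ``n_rows`` generated
    rows) and the absolute error.
    """
    if n_rows < 50:
        raise ValueError("recovery experiment needs n_rows >= 50")
    if structure is None:
        structure = default_structure()
    big = SyntheticSpec(
        n_rows, spec.true_R, spec.margin_specs, seed=seed, schema=spec.schema
    )
    table = generate(big)
    model = fit(table, structure, mode="bn_constrained")
    truth = true_arc_partials(spec, structure)
    rows = []
    for (s, d), rho_true in sorted(truth.items()):
        rho_fit = model.arc_partials[(s, d)]
        rows.append(
            {
                "source": s,
                "dest": d,
                "true_rho": rho_true,
                "fitted_rho": rho_fit,
                "abs_error": abs(rho_fit - rho_true),
            }
        )
    return pd.DataFrame(rows)
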