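"""One-site equilibrium binding model and nonlinear least-squares fitting.

The model is the standard steady-state saturation curve used for
surface-binding (SPR) affinity analysis,

    Y = Bmax · X / (Kd + X),

with X the analyte concentration (μM), Y the equilibrium response (R.U.),
Bmax the saturating response and Kd the dissociation constant.  Fitting is
unweighted least squares; positivity of both parameters is enforced by
optimizing in log-space, while standard errors are reported for the natural
parameters from the linearized covariance at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (ConvergenceError, DegenerateDataError, ParameterError)

MAX_ITERATIONS = 500


@dataclass
class BindingDataset:
    """Concentration/response table, optionally with replicate labels."""

    concentrations: np.ndarray  # μM
    responses: np.ndarray       # R.U.
    replicate_ids: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ParameterError("concentrations and responses must have equal length")
        if np.any(self.concentrations < 0):
            raise ParameterError("concentrations must be ≥ 0")

    def averaged(self) -> "BindingDataset":
        """Mean response per distinct concentration (duplicate pooling)."""
        conc = np.unique(self.concentrations)
        resp = np.array([self.responses[self.concentrations == c].mean() for c in conc])
        return BindingDataset(concentrations=conc, responses=resp,
                              metadata=dict(self.metadata))

    @classmethod
    def from_csv(cls, source) -> "BindingDataset":
        """Two-column CSV: concentration_uM, response_RU (header optional)."""
        import io
        text = source.read() if hasattr(source, "read") else open(source).read()
        conc, resp = [], []
        for line in io.StringIO(text):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            try:
                c, r = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                continue  # header line
            conc.append(c)
            resp.append(r)
        if not conc:
            raise DegenerateDataError("no numeric rows in binding CSV")
        return cls(concentrations=np.array(conc), responses=np.array(resp))

    def to_csv(self) -> str:
        lines = ["concentration_uM,response_RU"]
        lines += [f"{c:.6g},{r:.6f}" for c, r in zip(self.concentrations, self.responses)]
        return "\n".join(lines) + "\n"


@dataclass
class BindingFitResult:
    bmax: float          # R.U.
    kd: float            # μM
    bmax_se: float
    kd_se: float
    r_squared: float
    converged: bool
    n_points: int
    rss: float

    def to_dict(self) -> dict:
        return {
            "Bmax_RU": self.bmax, "Kd_uM": self.kd,
            "Bmax_SE": self.bmax_se, "Kd_SE": self.kd_se,
            "R2": self.r_squared, "converged": self.converged,
            "n_points": self.n_points, "rss": self.rss,
        }


def one_site_response(x, bmax: float, kd: float):
    """Y = Bmax·X/(Kd + X); scalar or array X in μM, Y in R.U."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterError("concentration must be ≥ 0")
    if bmax <= 0 or kd <= 0:
        raise ParameterError("Bmax and Kd must be positive")
    y = bmax * x / (kd + x)
    return float(y) if y.ndim == 0 else y


def fit_one_site(dataset: BindingDataset, average_duplicates: bool = True) -> BindingFitResult:
    """Least-squares fit of the one-site model to a binding dataset.

    Initial guesses: Bmax₀ = max(Y), Kd₀ = median(X>0).  R² = 1 − SS_res/SS_tot;
    standard errors come from (JᵀJ)⁻¹·s² with J the natural-parameter
    Jacobian at the optimum and s² = SS_res/(n−2).
    """
    data = dataset.averaged() if average_duplicates else dataset
    x, y = data.concentrations, data.responses
    if len(np.unique(x)) < 3:
        raise DegenerateDataError("need at least 3 distinct concentrations")
    if np.ptp(y) == 0.0:
        raise DegenerateDataError("responses are all equal; the model is unidentifiable")
    ymax = float(y.max())
    if ymax <= 0:
        raise DegenerateDataError("responses must contain positive values")
    # fit in normalized units (x/median, y/max): the optimization is then
    # exactly equivariant under rescaling of concentrations or responses
    sx = float(np.median(x[x > 0]))
    sy = ymax
    xn, yn = x / sx, y / sy

    def residuals(theta):
        bmax, kd = np.exp(theta)
        return bmax * xn / (kd + xn) - yn

    def jac(theta):
        bmax, kd = np.exp(theta)
        denom = kd + xn
        return np.column_stack([bmax * xn / denom,
                                -bmax * xn * kd / denom ** 2])

    sol = least_squares(residuals, np.zeros(2), jac=jac, method="lm",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14,
                        max_nfev=MAX_ITERATIONS)
    bmax, kd = np.exp(sol.x) * (sy, sx)
    if not sol.success:
        raise ConvergenceError(
            f"one-site fit did not converge in {MAX_ITERATIONS} evaluations: {sol.message}",
            last_iterate={"Bmax": bmax, "Kd": kd})

    resid = one_site_response(x, bmax, kd) - y
    rss = float(resid @ resid)
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / sstot if sstot > 0 else float("nan")

    # linearized covariance in the natural parameters
    denom = kd + x
    J = np.column_stack([x / denom, -bmax * x / denom ** 2])
    dof = max(len(x) - 2, 1)
    s2 = rss / dof
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        bmax_se, kd_se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        bmax_se = kd_se = float("nan")
    return BindingFitResult(bmax=float(bmax), kd=float(kd),
                            bmax_se=float(bmax_se), kd_se=float(kd_se),
                            r_squared=float(r2), converged=True,
                            n_points=len(x), rss=rss)
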