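"""Variance-based (Sobol) global sensitivity analysis of the kinetic
parameters: first-order indices S_i = V[E[Y|X_i]] / V[Y], aggregate and
time-resolved per observed metabolite.

Parameters are drawn uniformly over finite ranges (by default 0.5x-1.5x of
the fitted values) with a Saltelli-type paired design built on scrambled
Sobol' sequences: matrices A and B plus the k hybrids A_B^(i) in which
column i of A is replaced by column i of B, (k+2)*n model runs in total.
V[E[Y|X_i]] is estimated with the Jansen (1999) form

    V_i = V[Y] - (1/2n) * sum_j (f(B_j) - f(A_B^(i)_j))^2

which has lower estimator variance than the naive product form.  Only
first-order indices are computed: with 89 kinetic parameters the
higher-order interaction terms are computationally out of reach, and their
sum is bounded anyway (sum of first-order indices <= 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .model import MetabolicModel, ParameterSet
from .simulate import IntegrationError, observe, simulate

__all__ = [
    "SensitivitySpec",
    "SensitivityResult",
    "SaltelliSample",
    "sample_parameter_space",
    "saltelli_sample",
    "jansen_first_order",
    "sobol_indices",
    "evaluate_model_batch",
    "first_order_indices",
    "analyze",
    "rank_parameters",
]

DEFAULT_RANGE_FACTORS = (0.5, 1.5)
DEFAULT_OUTPUTS = ["Gln", "Glc", "Lac", "NH4"]  # glutamic acid excluded: it is
# consumed only by the viral-protein synthesis laws and carries almost no
# information about the rest of the network.


# ---------------------------------------------------------------------------
# generic estimator layer (usable on any function of uniform inputs)
# ---------------------------------------------------------------------------


@dataclass
class SaltelliSample:
    """Paired design matrices in natural parameter units."""

    A: np.ndarray          # (n, k)
    B: np.ndarray          # (n, k)
    AB: np.ndarray         # (k, n, k): AB[i] is A with column i from B

    @property
    def n_base(self) -> int:
        return self.A.shape[0]

    @property
    def k(self) -> int:
        return self.A.shape[1]

    @property
    def n_total(self) -> int:
        return (self.k + 2) * self.n_base

    def rows(self) -> np.ndarray:
        """All (k+2)*n parameter vectors stacked: A, B, AB_1..AB_k."""
        return np.vstack([self.A, self.B, self.AB.reshape(-1, self.k)])


def saltelli_sample(bounds: np.ndarray, n_base: int, seed: int) -> SaltelliSample:
    """Draw the A/B/A_B^(i) design over uniform ``bounds`` (shape (k, 2))."""
    bounds = np.asarray(bounds, dtype=float)
    k = bounds.shape[0]
    if np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("each range must satisfy lower < upper")
    if n_base < 2:
        raise ValueError("n_base_samples must be >= 2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non power-of-two n
        u = qmc.Sobol(d=2 * k, scramble=True, seed=seed).random(n_base)
    lo, span = bounds[:, 0], bounds[:, 1] - bounds[:, 0]
    A = lo + span * u[:, :k]
    B = lo + span * u[:, k:]
    AB = np.repeat(A[None, :, :], k, axis=0)
    for i in range(k):
        AB[i, :, i] = B[:, i]
    return SaltelliSample(A, B, AB)


def jansen_first_order(
    fA: np.ndarray, fB: np.ndarray, fAB: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Jansen estimate of all first-order indices from paired evaluations.

    ``fA``/``fB`` have shape (n,), ``fAB`` (k, n); NaN rows (failed model
    evaluations) are excluded pairwise.  Returns (S, total variance, mean);
    if the output variance is ~0 all indices are reported as 0.
    """
    fA = np.asarray(fA, dtype=float)
    fB = np.asarray(fB, dtype=float)
    fAB = np.asarray(fAB, dtype=float)
    both = np.concatenate([fA[np.isfinite(fA)], fB[np.isfinite(fB)]])
    f0 = float(np.mean(both))
    V = float(np.var(both))
    if V <= 1e-12 * max(1.0, f0**2):
        return np.zeros(fAB.shape[0]), V, f0
    S = np.empty(fAB.shape[0])
    for i in range(fAB.shape[0]):
        ok = np.isfinite(fB) & np.isfinite(fAB[i])
        S[i] = (V - 0.5 * np.mean((fB[ok] - fAB[i][ok]) ** 2)) / V
    return S, V, f0


def sobol_indices(
    func,
    bounds: np.ndarray,
    n_base: int,
    seed: int = 0,
    n_boot: int = 200,
) -> dict:
    """First-order indices of ``func(x)`` (x a (n, k) batch) over uniform
    inputs, with seeded percentile bootstrap confidence intervals.

    Returns a dict with keys ``S`` (k,), ``ci_low``, ``ci_high``,
    ``variance``, ``mean``.
    """
    design = saltelli_sample(np.asarray(bounds, dtype=float), n_base, seed)
    fA = np.asarray(func(design.A), dtype=float)
    fB = np.asarray(func(design.B), dtype=float)
    fAB = np.stack([np.asarray(func(design.AB[i]), dtype=float)
                    for i in range(design.k)])
    S, V, f0 = jansen_first_order(fA, fB, fAB)
    rng = np.random.default_rng(seed + 1)
    boots = np.empty((n_boot, design.k))
    for b in range(n_boot):
        idx = rng.integers(0, design.n_base, size=design.n_base)
        boots[b], _, _ = jansen_first_order(fA[idx], fB[idx], fAB[:, idx])
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return {"S": S, "ci_low": lo, "ci_high": hi, "variance": V, "mean": f0}


# ---------------------------------------------------------------------------
# model-facing layer
# ---------------------------------------------------------------------------


@dataclass
class SensitivitySpec:
    """What to vary, over which ranges, and which outputs to watch."""

    parameters: list[str]
    ranges: dict[str, tuple[float, float]]
    n_base_samples: int = 1024
    seed: int = 0
    outputs: list[str] = field(default_factory=lambda: list(DEFAULT_OUTPUTS))
    output_times: np.ndarray | None = None  # default: the 24 h sampling grid
    rtol: float = 1e-7
    atol: float = 1e-9

    def __post_init__(self):
        if self.n_base_samples < 2:
            raise ValueError("n_base_samples must be >= 2")
        missing = [p for p in self.parameters if p not in self.ranges]
        if missing:
            raise ValueError(f"no range given for: {missing}")
        for p in self.parameters:
            lo, hi = self.ranges[p]
            if not lo < hi:
                raise ValueError(f"range for {p!r} must satisfy lower < upper")

    def bounds_array(self) -> np.ndarray:
        return np.array([self.ranges[p] for p in self.parameters])


def default_spec(
    model: MetabolicModel,
    subset: str = "vmax",
    factors: tuple[float, float] = DEFAULT_RANGE_FACTORS,
    **kwargs,
) -> SensitivitySpec:
    """Spec varying the vmax group, the Km group, or all kinetic parameters
    over ``factors`` x their fitted values."""
    base = model.parameter_set()
    if subset == "vmax":
        names = list(model.vmax_names)
    elif subset == "Km":
        names = list(model.km_names)
    elif subset == "all":
        names = list(model.vmax_names) + list(model.km_names)
    else:
        raise ValueError("subset must be 'vmax', 'Km' or 'all'")
    ranges = {n: (factors[0] * base[n], factors[1] * base[n]) for n in names}
    return SensitivitySpec(parameters=names, ranges=ranges, **kwargs)


def sample_parameter_space(spec: SensitivitySpec) -> SaltelliSample:
    """The Saltelli design for a spec: (k+2) * n_base parameter vectors."""
    return saltelli_sample(spec.bounds_array(), spec.n_base_samples, spec.seed)


def evaluate_model_batch(
    model: MetabolicModel,
    samples: np.ndarray,
    spec: SensitivitySpec,
    base_params: ParameterSet | None = None,
) -> tuple[np.ndarray, int]:
    """Simulate once per sample row; unsampled parameters stay at fitted
    values.

    Returns (Y, n_failed) with Y of shape (n_rows, n_outputs, n_times);
    failed integrations are NaN rows, excluded pairwise by the estimator.
    More than 10% failures raises a diagnostic error (the ranges are
    probably too wide for the solver).
    """
    if base_params is None:
        base_params = model.parameter_set()
    t = (np.asarray(spec.output_times, dtype=float)
         if spec.output_times is not None else None)
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    Y = None
    n_failed = 0
    for r, row in enumerate(samples):
        params = base_params.updated(dict(zip(spec.parameters, row)))
        try:
            traj = simulate(model, params, t, rtol=spec.rtol, atol=spec.atol)
            prof = observe(traj, order=list(spec.outputs))
            if Y is None:
                Y = np.full((len(samples),) + prof.values.T.shape, np.nan)
            Y[r] = prof.values.T  # (n_outputs, n_times)
        except IntegrationError:
            n_failed += 1
    if Y is None:
        raise IntegrationError("every sampled parameter vector failed", 0.0)
    if n_failed > 0.1 * len(samples):
        raise RuntimeError(
            f"{n_failed}/{len(samples)} integrations failed; "
            "narrower parameter ranges are advisable"
        )
    return Y, n_failed


def _scalarize(Y: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Collapse (n, n_outputs, n_times) to one number per run: the mean
    over outputs and times of |y(t) - y(0)| / scale_output."""
    dev = np.abs(Y - Y[:, :, :1])
    return np.nanmean(dev / scales[None, :, None], axis=(1, 2))


@dataclass
class SensitivityResult:
    """First-order Sobol indices, aggregate and per output/time."""

    parameters: list[str]
    kinds: dict[str, str]
    first_order: dict[str, float]                 # aggregate S_i
    ci: dict[str, tuple[float, float]]            # bootstrap 95% CI
    time_resolved: np.ndarray                     # (n_outputs, n_times, k)
    outputs: list[str]
    times: np.ndarray
    total_variance: dict[str, np.ndarray]         # per output, over time
    mean: dict[str, np.ndarray]                   # f_0 per output, over time
    aggregate_variance: float
    n_failed: int
    degenerate: bool

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (parameter, output, time)."""
        rows = []
        for j, p in enumerate(self.parameters):
            lo, hi = self.ci[p]
            rows.append({"parameter": p, "output": "aggregate", "time_h": np.nan,
                         "S1": self.first_order[p], "ci_low": lo, "ci_high": hi})
            for a, out in enumerate(self.outputs):
                for b, t in enumerate(self.times):
                    rows.append({"parameter": p, "output": out, "time_h": t,
                                 "S1": self.time_resolved[a, b, j],
                                 "ci_low": np.nan, "ci_high": np.nan})
        return pd.DataFrame(rows)


def first_order_indices(
    spec: SensitivitySpec,
    design: SaltelliSample,
    Y: np.ndarray,
    param_kinds: dict[str, str] | None = None,
    n_boot: int = 200,
) -> SensitivityResult:
    """Estimate aggregate and time-resolved indices from batch outputs.

    ``Y`` is the (n_rows, n_outputs, n_times) array from
    :func:`evaluate_model_batch`, rows ordered A, B, AB_1..AB_k.
    """
    n, k = design.n_base, design.k
    YA, YB = Y[:n], Y[n:2 * n]
    YAB = Y[2 * n:].reshape(k, n, *Y.shape[1:])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        # typical magnitude per output, so no single metabolite dominates and
        # outputs that start near 0 do not blow up the normalization
        scales = np.maximum(np.nanmean(np.abs(Y), axis=(0, 2)), 1e-6)
    gA, gB = _scalarize(YA, scales), _scalarize(YB, scales)
    gAB = np.stack([_scalarize(YAB[i], scales) for i in range(k)])
    S_agg, V_agg, _ = jansen_first_order(gA, gB, gAB)

    rng = np.random.default_rng(spec.seed + 1)
    boots = np.empty((n_boot, k))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b], _, _ = jansen_first_order(gA[idx], gB[idx], gAB[:, idx])
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)

    n_out, n_t = Y.shape[1], Y.shape[2]
    tr = np.zeros((n_out, n_t, k))
    variances = {out: np.zeros(n_t) for out in spec.outputs}
    means = {out: np.zeros(n_t) for out in spec.outputs}
    for a in range(n_out):
        for b in range(n_t):
            S, V, f0 = jansen_first_order(
                YA[:, a, b], YB[:, a, b], YAB[:, :, a, b]
            )
            tr[a, b] = S
            variances[spec.outputs[a]][b] = V
            means[spec.outputs[a]][b] = f0

    times = (np.asarray(spec.output_times, dtype=float)
             if spec.output_times is not None
             else np.arange(0.0, 121.0, 24.0))
    return SensitivityResult(
        parameters=list(spec.parameters),
        kinds=param_kinds or {},
        first_order=dict(zip(spec.parameters, S_agg)),
        ci={p: (float(l), float(h))
            for p, l, h in zip(spec.parameters, lo, hi)},
        time_resolved=tr,
        outputs=list(spec.outputs),
        times=times,
        total_variance=variances,
        mean=means,
        aggregate_variance=V_agg,
        n_failed=int(np.sum(~np.isfinite(Y[:, 0, 0]))),
        degenerate=bool(V_agg <= 1e-12),
    )


def analyze(
    model: MetabolicModel,
    spec: SensitivitySpec,
    base_params: ParameterSet | None = None,
    n_boot: int = 200,
) -> SensitivityResult:
    """Full SGSA pipeline: sample, simulate the batch, estimate indices."""
    design = sample_parameter_space(spec)
    Y, _ = evaluate_model_batch(model, design.rows(), spec, base_params)
    kinds = {}
    for p in spec.parameters:
        if p in model.vmax_names:
            kinds[p] = "vmax"
        elif p in model.km_names:
            kinds[p] = "Km"
    return first_order_indices(spec, design, Y, kinds, n_boot)


def rank_parameters(
    result: SensitivityResult, group: str | None = None
) -> pd.DataFrame:
    """Descending aggregate ranking with cumulative explained variance.

    ``group`` restricts to "vmax" or "Km" parameters; ties are broken by
    parameter name so the ordering is deterministic.
    """
    items = [
        (p, s) for p, s in result.first_order.items()
        if group is None or result.kinds.get(p) == group
    ]
    items.sort(key=lambda ps: (-ps[1], ps[0]))
    df = pd.DataFrame(items, columns=["parameter", "S1"])
    df["cumulative_S1"] = df["S1"].cumsum()
    return df
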