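"""Closed-population capture-recapture with conditional (Huggins) likelihood.

Capture probabilities are modelled on the logit scale as combinations of
time effects (t), a permanent trap-response behaviour effect (b), and
individual-covariate heterogeneity (h, linear or quadratic), giving the
classical eight closed-population models M(0) ... M(tbh).  The likelihood is
conditioned on each animal being caught at least once, so abundance N never
enters the likelihood; it is recovered afterwards by Horvitz-Thompson
summation of 1/pi_i over the D observed animals, with a variance that adds a
binomial term to a delta-method term over the coefficient covariance
(Huggins 1989).  Model choice is by AIC.

The behaviour effect enters only recapture probabilities: pi_i (the
probability of being caught at least once) is built from first-capture
probabilities, since an animal that has never been caught cannot have
responded to a trap.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import optimize

MODEL_ORDER = ["M0", "Mt", "Mb", "Mh", "Mh2", "Mtb", "Mth", "Mbh", "Mtbh"]


@dataclass
class CaptureHistory:
    """Binary detections of D observed animals over T ordered occasions."""

    individuals: list[str]
    occasions: list[str]
    detections: np.ndarray  # (D, T) in {0,1}
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    covariate_norms: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.detections = np.asarray(self.detections, dtype=np.int8)
        D, T = len(self.individuals), len(self.occasions)
        if self.detections.shape != (D, T):
            raise ValueError("detections shape mismatch")
        if ((self.detections != 0) & (self.detections != 1)).any():
            raise ValueError("detections must be binary")
        if D and (self.detections.sum(axis=1) == 0).any():
            raise ValueError("every observed individual needs >= 1 detection")
        for name, v in self.covariates.items():
            if len(v) != D:
                raise ValueError(f"covariate {name!r} length mismatch")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    @property
    def total_captures(self) -> int:
        return int(self.detections.sum())


def read_capture_csv(path: str | Path, covariate_columns: list[str] | None = None) -> CaptureHistory:
    """Read capture events (one row per capture) into a CaptureHistory.

    Columns: ``individual``, ``occasion``, plus numeric covariate columns.
    Occasions are ordered by first appearance in the file; repeated captures
    of an individual within one occasion collapse to a single detection.
    Covariates are taken from the first row mentioning the individual
    (assumed constant).
    """
    path = Path(path)
    with path.open() as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "individual" not in reader.fieldnames:
            raise ValueError("capture file needs 'individual' and 'occasion' columns")
        if "occasion" not in reader.fieldnames:
            raise ValueError("capture file needs 'individual' and 'occasion' columns")
        if covariate_columns is None:
            covariate_columns = [
                c for c in reader.fieldnames if c not in ("individual", "occasion")
            ]
        rows = list(reader)
    occasions: list[str] = []
    individuals: list[str] = []
    cov_first: dict[str, dict[str, float]] = {}
    events: set[tuple[str, str]] = set()
    for row in rows:
        ind, occ = row["individual"].strip(), row["occasion"].strip()
        if occ not in occasions:
            occasions.append(occ)
        if ind not in cov_first:
            individuals.append(ind)
            cov_first[ind] = {c: float(row[c]) for c in covariate_columns}
        events.add((ind, occ))
    det = np.zeros((len(individuals), len(occasions)), dtype=np.int8)
    ind_ix = {v: i for i, v in enumerate(individuals)}
    occ_ix = {v: j for j, v in enumerate(occasions)}
    for ind, occ in events:
        det[ind_ix[ind], occ_ix[occ]] = 1
    covs = {
        c: np.array([cov_first[ind][c] for ind in individuals])
        for c in covariate_columns
    }
    return CaptureHistory(individuals, occasions, det, covs)


def write_capture_csv(ch: CaptureHistory, path: str | Path) -> None:
    """Write one row per (individual, occasion) detection, with covariates."""
    cov_names = list(ch.covariates)
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual", "occasion", *cov_names])
        # occasion-major so the reader recovers the occasion order
        for j, occ in enumerate(ch.occasions):
            for i, ind in enumerate(ch.individuals):
                if ch.detections[i, j]:
                    w.writerow(
                        [ind, occ, *(ch.covariates[c][i] for c in cov_names)]
                    )


def pool_occasions(ch: CaptureHistory, grouping: dict[str, list[str]]) -> CaptureHistory:
    """Merge occasions; a pooled detection is the OR of its members.

    ``grouping`` maps pooled labels to lists of existing occasion labels and
    must partition the occasion set.  Pooled occasions take the position of
    their earliest member.
    """
    members = [occ for group in grouping.values() for occ in group]
    if sorted(members) != sorted(ch.occasions) or len(set(members)) != len(members):
        raise ValueError("grouping must partition the occasion labels")
    occ_ix = {v: j for j, v in enumerate(ch.occasions)}
    order = sorted(grouping, key=lambda g: min(occ_ix[o] for o in grouping[g]))
    det = np.zeros((ch.n_individuals, len(order)), dtype=np.int8)
    for k, g in enumerate(order):
        cols = [occ_ix[o] for o in grouping[g]]
        det[:, k] = ch.detections[:, cols].max(axis=1)
    return CaptureHistory(
        list(ch.individuals), order, det,
        {k: v.copy() for k, v in ch.covariates.items()},
        dict(ch.covariate_norms),
    )


def normalize_covariates(ch: CaptureHistory, names: list[str]) -> CaptureHistory:
    """z-score the named covariates (mean 0, sd 1; denominator n).

    Transform parameters are stored in ``covariate_norms`` for
    reproducibility.
    """
    covs = {k: v.copy() for k, v in ch.covariates.items()}
    norms = dict(ch.covariate_norms)
    for name in names:
        if name not in covs:
            raise KeyError(f"unknown covariate {name!r}")
        v = covs[name].astype(float)
        mu, sd = float(v.mean()), float(v.std(ddof=0))
        if sd == 0:
            raise ValueError(f"covariate {name!r} has zero variance")
        covs[name] = (v - mu) / sd
        norms[name] = (mu, sd)
    return CaptureHistory(
        list(ch.individuals), list(ch.occasions), ch.detections.copy(), covs, norms
    )


@dataclass(frozen=True)
class CMRModelSpec:
    """One cell of the M(0)/M(t)/M(b)/M(h) model family."""

    time_effect: bool = False
    behavior_effect: bool = False
    heterogeneity: str = "none"  # none | linear | quadratic
    covariate: str | None = None

    def __post_init__(self) -> None:
        if self.heterogeneity not in ("none", "linear", "quadratic"):
            raise ValueError("heterogeneity must be none|linear|quadratic")
        if self.heterogeneity != "none" and self.covariate is None:
            raise ValueError("heterogeneity models need a covariate name")

    @property
    def name(self) -> str:
        tags = ""
        if self.time_effect:
            tags += "t"
        if self.behavior_effect:
            tags += "b"
        if self.heterogeneity != "none":
            tags += "h"
        base = f"M{tags}" if tags else "M0"
        return base + ("2" if self.heterogeneity == "quadratic" else "")

    def n_params(self, T: int) -> int:
        k = 1
        if self.time_effect:
            k += T - 1
        if self.behavior_effect:
            k += 1
        if self.heterogeneity == "linear":
            k += 1
        elif self.heterogeneity == "quadratic":
            k += 2
        return k


def _design(ch: CaptureHistory, spec: CMRModelSpec):
    """Design arrays X (with behaviour column) and X1 (first-capture)."""
    D, T = ch.n_individuals, ch.n_occasions
    P = spec.n_params(T)
    X = np.zeros((D, T, P))
    X[:, :, 0] = 1.0
    col = 1
    if spec.time_effect:
        for j in range(1, T):
            X[:, j, col + j - 1] = 1.0
        col += T - 1
    b_col = None
    if spec.behavior_effect:
        b_col = col
        prior = np.zeros((D, T))
        prior[:, 1:] = np.cumsum(ch.detections[:, :-1], axis=1) > 0
        X[:, :, col] = prior
        col += 1
    if spec.heterogeneity != "none":
        z = ch.covariates[spec.covariate].astype(float)
        X[:, :, col] = z[:, None]
        col += 1
        if spec.heterogeneity == "quadratic":
            X[:, :, col] = (z**2)[:, None]
            col += 1
    X1 = X.copy()
    if b_col is not None:
        X1[:, :, b_col] = 0.0
    return X, X1


def capture_probability(
    spec: CMRModelSpec,
    params: np.ndarray,
    T: int,
    occasion: int = 0,
    covariate_value: float = 0.0,
    previously_captured: bool = False,
) -> float:
    """Inverse-logit capture probability for one animal-occasion cell."""
    params = np.asarray(params, dtype=float)
    if params.size != spec.n_params(T):
        raise ValueError(
            f"expected {spec.n_params(T)} parameters, got {params.size}"
        )
    eta = params[0]
    col = 1
    if spec.time_effect:
        if not 0 <= occasion < T:
            raise ValueError("occasion index out of range")
        if occasion >= 1:
            eta += params[col + occasion - 1]
        col += T - 1
    if spec.behavior_effect:
        eta += params[col] * previously_captured
        col += 1
    if spec.heterogeneity != "none":
        eta += params[col] * covariate_value
        col += 1
        if spec.heterogeneity == "quadratic":
            eta += params[col] * covariate_value**2
    return float(1.0 / (1.0 + math.exp(-eta)))


@dataclass
class CMRFit:
    spec: CMRModelSpec
    coefficients: np.ndarray
    log_lik: float
    aic: float
    N_hat: float
    se_N_hat: float
    converged: bool
    boundary: bool = False
    message: str = ""
    coef_cov: np.ndarray | None = None

    @property
    def name(self) -> str:
        return self.spec.name

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        return self.N_hat - z * self.se_N_hat, self.N_hat + z * self.se_N_hat


def _nll_grad(beta: np.ndarray, X: np.ndarray, X1: np.ndarray, y: np.ndarray):
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    eta1 = X1 @ beta
    p1 = 1.0 / (1.0 + np.exp(-eta1))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    p1 = np.clip(p1, 1e-12, 1 - 1e-12)
    log_miss = np.log1p(-p1).sum(axis=1)  # log prod (1 - p1_ij)
    pi = -np.expm1(log_miss)
    pi = np.clip(pi, 1e-12, 1.0)
    ll = (y * np.log(p) + (1 - y) * np.log1p(-p)).sum() - np.log(pi).sum()
    # gradient
    resid = y - p  # (D, T)
    g_bern = np.einsum("dt,dtp->p", resid, X)
    w = (np.exp(log_miss) / pi)[:, None] * p1  # (D, T)
    g_pi = np.einsum("dt,dtp->p", w, X1)
    return -ll, -(g_bern - g_pi)


def _fit_metrics(beta: np.ndarray, X: np.ndarray, X1: np.ndarray, y: np.ndarray):
    nll, _ = _nll_grad(beta, X, X1, y)
    eta1 = X1 @ beta
    p1 = np.clip(1.0 / (1.0 + np.exp(-eta1)), 1e-12, 1 - 1e-12)
    log_miss = np.log1p(-p1).sum(axis=1)
    pi = np.clip(-np.expm1(log_miss), 1e-12, 1.0)
    N_hat = float((1.0 / pi).sum())
    var_binom = float(((1 - pi) / pi**2).sum())
    # dN/dbeta = -sum_i (1-pi_i)/pi_i^2 * sum_j p1_ij x1_ij
    w = ((1 - pi) / pi**2)[:, None] * p1
    dN = -np.einsum("dt,dtp->p", w, X1)
    # observed information via central differences of the analytic gradient
    P = beta.size
    H = np.zeros((P, P))
    h = 1e-5 * np.maximum(1.0, np.abs(beta))
    for k in range(P):
        bp, bm = beta.copy(), beta.copy()
        bp[k] += h[k]
        bm[k] -= h[k]
        _, gp = _nll_grad(bp, X, X1, y)
        _, gm = _nll_grad(bm, X, X1, y)
        H[:, k] = (gp - gm) / (2 * h[k])
    H = (H + H.T) / 2
    try:
        cov = np.linalg.inv(H)
        var_delta = float(dN @ cov @ dN)
        if var_delta < 0:
            var_delta = 0.0
    except np.linalg.LinAlgError:
        cov = None
        var_delta = float("nan")
    se = math.sqrt(var_binom + var_delta)
    boundary = bool(p1.max() > 0.999)
    return -nll, N_hat, se, boundary, cov


def fit_huggins(
    ch: CaptureHistory,
    spec: CMRModelSpec,
    n_restarts: int = 2,
    seed: int = 0,
    gtol: float = 1e-8,
) -> CMRFit:
    """Maximise the conditional likelihood and estimate abundance.

    Starts from the logit of the naive capture fraction (other coefficients
    0) plus ``n_restarts`` jittered restarts with a fixed seed; the best
    converged optimum wins.  N_hat = sum_i 1/pi_i; its standard error
    combines the binomial term sum (1-pi)/pi^2 with a delta-method term over
    the observed-information covariance of the coefficients.
    """
    if ch.n_occasions < 2:
        raise ValueError("need >= 2 occasions")
    if ch.n_individuals < 1:
        raise ValueError("no observed individuals")
    if spec.heterogeneity != "none" and spec.covariate not in ch.covariates:
        raise KeyError(f"missing covariate column {spec.covariate!r}")
    X, X1 = _design(ch, spec)
    y = ch.detections.astype(float)
    P = spec.n_params(ch.n_occasions)
    frac = min(max(y.mean(), 1e-3), 1 - 1e-3)
    base = np.zeros(P)
    base[0] = math.log(frac / (1 - frac))
    rng = np.random.default_rng(seed)
    starts = [base] + [
        base + rng.normal(scale=0.5, size=P) for _ in range(n_restarts)
    ]
    best = None
    any_ok = False
    for s in starts:
        res = optimize.minimize(
            _nll_grad, s, args=(X, X1, y), jac=True, method="BFGS",
            options={"gtol": gtol, "maxiter": 500},
        )
        ok = bool(res.success) or float(np.linalg.norm(res.jac)) < 1e-4
        if best is None or res.fun < best[0].fun - 1e-10:
            best = (res, ok)
        any_ok = any_ok or ok
    res, ok = best
    ll, N_hat, se, boundary, cov = _fit_metrics(res.x, X, X1, y)
    aic = -2 * ll + 2 * P
    return CMRFit(
        spec=spec, coefficients=res.x, log_lik=ll, aic=aic, N_hat=N_hat,
        se_N_hat=se, converged=ok, boundary=boundary, message=str(res.message),
        coef_cov=cov,
    )


def all_model_specs(covariate: str | None = None, include_quadratic: bool = False) -> list[CMRModelSpec]:
    specs = []
    for t in (False, True):
        for b in (False, True):
            for h in (("none",) if covariate is None else ("none", "linear")):
                specs.append(
                    CMRModelSpec(t, b, h, covariate if h != "none" else None)
                )
    if include_quadratic and covariate is not None:
        specs.append(CMRModelSpec(False, False, "quadratic", covariate))
    return sorted(specs, key=lambda s: MODEL_ORDER.index(s.name))


def fit_all_models(
    ch: CaptureHistory,
    covariate: str | None = None,
    include_quadratic: bool = False,
    seed: int = 0,
) -> list[CMRFit]:
    """Fit the eight-model family (plus quadratic M(h) when flagged).

    Per-model failures are captured as unconverged fits rather than aborting
    the sweep.  Results are sorted by AIC.
    """
    fits: list[CMRFit] = []
    for spec in all_model_specs(covariate, include_quadratic):
        try:
            fits.append(fit_huggins(ch, spec, seed=seed))
        except Exception as exc:  # noqa: BLE001 - sweep must not abort
            fits.append(
                CMRFit(
                    spec=spec, coefficients=np.full(spec.n_params(ch.n_occasions), np.nan),
                    log_lik=float("nan"), aic=float("inf"), N_hat=float("nan"),
                    se_N_hat=float("nan"), converged=False, message=str(exc),
                )
            )
    return sorted(fits, key=lambda f: (f.aic, f.name))


def select_model(fits: list[CMRFit]) -> CMRFit:
    """Minimum-AIC converged fit; ties go to fewer parameters, then to the
    canonical model order M(0), M(t), M(b), M(h), ..."""
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise ValueError("no converged fit to select from")
    return min(
        ok,
        key=lambda f: (
            f.aic, f.coefficients.size, MODEL_ORDER.index(f.name),
        ),
    )
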