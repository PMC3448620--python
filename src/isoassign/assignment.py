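"""Likelihood-based assignment of feather isotope triplets to isotopic clusters.

The inference chain:

1. Estimate the mean and 3×3 covariance Σ of (δ²H_f, δ¹³C_f, δ¹⁵N_f) across
   the feather sample by maximum likelihood under a multivariate normal with
   values missing completely at random — an EM algorithm (`fit_mvn_missing`).
2. For each individual x, evaluate the MVN density f(x; μ_k, Σ) against each
   cluster's expected isotope mean μ_k (zonal means of the feather
   isoscapes) and normalize across clusters (`normalized_cluster_probs`) —
   equal priors, so with the shared Σ this is nearest-mean assignment in
   Mahalanobis distance.
3. Propagate isotopic variance by repeating the assignment over simulated
   draws x* ~ MVN(x, Σ_sim) (`simulate_assignments`), reporting per-cluster
   mean ± SD counts across replicates (`summarize_counts`).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from isoassign.grids import ClusterSummary

__all__ = [
    "FeatherRecord", "MvnFit", "AssignmentMatrix", "PopulationSummary",
    "fit_mvn_missing", "log_mvn_density", "normalized_cluster_probs",
    "simulate_assignments", "summarize_counts",
    "read_feather_csv", "write_feather_csv", "select_assignable",
    "records_to_matrix", "ConvergenceError",
]

ISOTOPES = ("d2h", "d13c", "d15n")


class ConvergenceError(RuntimeError):
    """EM failed to converge within the iteration budget."""


@dataclasses.dataclass
class FeatherRecord:
    """One feather sample: isotope triplet (‰, NaN = not measured) + metadata.

    Hatch-year (``age='HY'``) feathers were grown on the European breeding
    grounds and are excluded from African assignment by `select_assignable`.
    """

    sample_id: str
    ring: str = ""
    year: int | None = None
    age: str = "adult"
    d2h: float = np.nan
    d13c: float = np.nan
    d15n: float = np.nan
    sex: str | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d2h) or np.isfinite(self.d13c)
                or np.isfinite(self.d15n)):
            raise ValueError(f"record {self.sample_id}: no isotope observed")

    @property
    def triplet(self) -> np.ndarray:
        return np.array([self.d2h, self.d13c, self.d15n], dtype=float)

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.triplet)))


@dataclasses.dataclass
class MvnFit:
    """ML mean/covariance of the feather isotope distribution (n divisor)."""

    mean: np.ndarray
    cov: np.ndarray
    n_records: int
    n_complete: int
    em_iterations: int
    converged: bool

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")
        eigmin = np.linalg.eigvalsh(self.cov).min()
        if eigmin < -1e-8 * np.trace(self.cov):
            raise ValueError("covariance is not positive semi-definite")

    def require_converged(self) -> None:
        if not self.converged:
            raise ConvergenceError(
                f"EM did not converge in {self.em_iterations} iterations")


@dataclasses.dataclass
class AssignmentMatrix:
    """Per-individual cluster probabilities and simulation frequencies.

    ``probs[i, k]``: normalized point-assignment probability of cluster k.
    ``frequencies[i, k]``: fraction of replicates in which individual i was
    assigned (argmax) to cluster k.  ``replicate_counts[s, k]``: number of
    individuals assigned to k in replicate s.
    """

    sample_ids: list[str]
    cluster_ids: np.ndarray
    probs: np.ndarray
    frequencies: np.ndarray
    modal_cluster: np.ndarray
    replicate_counts: np.ndarray
    n_sims: int
    seed: int | None

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        data = {"sample_id": self.sample_ids}
        for j, cid in enumerate(self.cluster_ids):
            data[f"p_cluster{cid}"] = self.probs[:, j]
        for j, cid in enumerate(self.cluster_ids):
            data[f"freq_cluster{cid}"] = self.frequencies[:, j]
        data["modal_cluster"] = self.modal_cluster
        return pd.DataFrame(data)


@dataclasses.dataclass
class PopulationSummary:
    """Mean ± SD number of individuals per cluster across simulations."""

    cluster_ids: np.ndarray
    mean_counts: np.ndarray
    sd_counts: np.ndarray
    n_individuals: int
    n_sims: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cluster": self.cluster_ids,
                             "mean_count": self.mean_counts,
                             "sd_count": self.sd_counts})


# ---------------------------------------------------------------------------
# Record I/O and filtering

def records_to_matrix(records: Sequence[FeatherRecord]) -> np.ndarray:
    """(n, 3) array of isotope triplets with NaN for missing values."""
    return np.array([r.triplet for r in records], dtype=float).reshape(-1, 3)


def read_feather_csv(path) -> list[FeatherRecord]:
    """Read feather samples from CSV; empty isotope fields become NaN.

    Expected columns: sample_id, ring, year, age, sex, d2h, d13c, d15n
    (ring/year/age/sex optional).
    """
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        year = row.get("year")
        records.append(FeatherRecord(
            sample_id=str(row["sample_id"]),
            ring=str(row.get("ring", "") or ""),
            year=int(year) if pd.notna(year) else None,
            age=str(row.get("age", "adult") or "adult"),
            d2h=float(row.get("d2h", np.nan)),
            d13c=float(row.get("d13c", np.nan)),
            d15n=float(row.get("d15n", np.nan)),
            sex=row.get("sex") if pd.notna(row.get("sex")) else None,
        ))
    return records


def write_feather_csv(records: Sequence[FeatherRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)


def select_assignable(records: Sequence[FeatherRecord],
                      exclude_years: Sequence[int] = (),
                      ages: Sequence[str] = ("adult",),
                      require_complete: bool = True,
                      collapse_rings: bool = False) -> list[FeatherRecord]:
    """Filter records for assignment.

    HY feathers (grown in Europe) are dropped by the default age filter;
    ``exclude_years`` supports manual exclusion of climatically anomalous
    years.  Repeated captures of the same ring are separate molt events by
    default; ``collapse_rings`` keeps only the latest year per ring.
    """
    out = [r for r in records if r.age in ages]
    if exclude_years:
        out = [r for r in out if r.year not in set(exclude_years)]
    if require_complete:
        out = [r for r in out if r.complete]
    if collapse_rings:
        byring: dict[str, FeatherRecord] = {}
        for r in out:
            key = r.ring or r.sample_id
            prev = byring.get(key)
            if prev is None or (r.year or 0) > (prev.year or 0):
                byring[key] = r
        out = list(byring.values())
    return out


# ---------------------------------------------------------------------------
# EM estimation of the MVN mean/covariance under MCAR missingness

def _ridge_if_singular(S: np.ndarray) -> np.ndarray:
    try:
        np.linalg.cholesky(S)
        return S
    except np.linalg.LinAlgError:
        warnings.warn("singular observed-block covariance; adding ridge",
                      RuntimeWarning, stacklevel=3)
        return S + 1e-8 * np.trace(S) * np.eye(S.shape[0])


def fit_mvn_missing(records, tol: float = 1e-8, max_iter: int = 1000) -> MvnFit:
    """ML mean and covariance of the isotope triplet with missing values.

    EM for the multivariate normal under MAR/MCAR: the E-step replaces the
    missing block of each record by its conditional mean given the observed
    block and adds the conditional covariance to the second-moment
    accumulator; the M-step re-estimates μ and Σ (n divisor).  Stops when
    the largest absolute change in any parameter drops below ``tol``.

    ``records`` may be FeatherRecords or an (n, d) array with NaN for
    missing entries.
    """
    if isinstance(records, np.ndarray):
        X = np.asarray(records, dtype=float)
    else:
        X = records_to_matrix(records)
    n, d = X.shape
    if n < 4:
        raise ValueError("need at least 4 records")
    obs = np.isfinite(X)
    if np.any(obs.sum(axis=0) < 2):
        raise ValueError("every isotope must be observed in >= 2 records")
    if np.any(~obs.any(axis=1)):
        raise ValueError("records with no observed isotope are not allowed")

    # available-case initialization
    mu = np.array([X[obs[:, j], j].mean() for j in range(d)])
    var = np.array([X[obs[:, j], j].var(ddof=0) for j in range(d)])
    cov = np.diag(np.maximum(var, 1e-12))

    patterns: dict[tuple, np.ndarray] = {}
    for key in {tuple(row) for row in obs}:
        patterns[key] = np.where((obs == np.asarray(key)).all(axis=1))[0]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sum_x = np.zeros(d)
        sum_xx = np.zeros((d, d))
        for key, idx in patterns.items():
            o = np.asarray(key)
            m = ~o
            Xo = X[np.ix_(idx, np.where(o)[0])]
            if not m.any():
                sum_x += Xo.sum(axis=0)
                sum_xx += Xo.T @ Xo
                continue
            Soo = _ridge_if_singular(cov[np.ix_(o, o)])
            Smo = cov[np.ix_(m, o)]
            reg = Smo @ np.linalg.inv(Soo)
            cond_cov = cov[np.ix_(m, m)] - reg @ Smo.T
            Xm_hat = mu[m] + (Xo - mu[o]) @ reg.T
            Xc = np.empty((len(idx), d))
            Xc[:, o] = Xo
            Xc[:, m] = Xm_hat
            sum_x += Xc.sum(axis=0)
            sum_xx += Xc.T @ Xc
            # conditional covariance enters the mm block once per record
            mm = np.ix_(m, m)
            sum_xx[mm] += len(idx) * cond_cov
        mu_new = sum_x / n
        cov_new = sum_xx / n - np.outer(mu_new, mu_new)
        cov_new = (cov_new + cov_new.T) / 2
        delta = max(np.abs(mu_new - mu).max(), np.abs(cov_new - cov).max())
        mu, cov = mu_new, cov_new
        if delta < tol:
            converged = True
            break

    n_complete = int(obs.all(axis=1).sum())
    return MvnFit(mean=mu, cov=cov, n_records=n, n_complete=n_complete,
                  em_iterations=it, converged=converged)


# ---------------------------------------------------------------------------
# MVN density and normalized cluster probabilities

def log_mvn_density(x: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float:
    """Exact log density of MVN(mu, cov) at x, via Cholesky.

    log f = −½ [d·log 2π + log|Σ| + (x−μ)ᵀ Σ⁻¹ (x−μ)]
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    cov = np.asarray(cov, dtype=float)
    d = x.shape[-1]
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance is not positive definite") from exc
    z = np.linalg.solve(L, (x - mu))
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return float(-0.5 * (d * np.log(2 * np.pi) + logdet + z @ z))


def _log_densities_matrix(X: np.ndarray, mus: np.ndarray,
                          cov: np.ndarray) -> np.ndarray:
    """Log MVN densities for rows of X against each mean row of mus.

    Shared covariance; returns shape ``X.shape[:-1] + (K,)``.
    """
    from scipy.linalg import solve_triangular

    L = np.linalg.cholesky(cov)
    d = mus.shape[1]
    K = mus.shape[0]
    logdet = 2.0 * np.log(np.diag(L)).sum()
    flat = X.reshape(-1, d)
    diff = flat[:, None, :] - mus[None, :, :]  # (n, K, d)
    z = solve_triangular(L, diff.reshape(-1, d).T, lower=True)
    maha = (z ** 2).sum(axis=0).reshape(flat.shape[0], K)
    out = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
    return out.reshape(X.shape[:-1] + (K,))


def normalized_cluster_probs(x, summary: ClusterSummary, fit: MvnFit,
                             policy: str = "strict") -> np.ndarray:
    """Normalized MVN probabilities of each cluster for one feather triplet.

    p_k = f(x; μ_k, Σ) / Σ_j f(x; μ_j, Σ) with equal cluster priors,
    computed through log-sum-exp.  Under the default strict policy the
    record must be complete; ``policy='marginal'`` uses the observed
    sub-vector with the matching sub-blocks of μ_k and Σ (the single- and
    two-isotope assignment mode).
    """
    if isinstance(x, FeatherRecord):
        x = x.triplet
    x = np.asarray(x, dtype=float)
    fit.require_converged()
    obs = np.isfinite(x)
    if not obs.all():
        if policy != "marginal":
            raise ValueError(
                "incomplete record under strict policy; use policy='marginal'")
        if not obs.any():
            raise ValueError("no observed isotope")
    mus = summary.mean_vectors()[:, obs]
    cov = fit.cov[np.ix_(obs, obs)]
    logf = np.array([log_mvn_density(x[obs], mu, cov) for mu in mus])
    return np.exp(logf - logsumexp(logf))


# ---------------------------------------------------------------------------
# Simulation-based uncertainty propagation

def simulate_assignments(records, summary: ClusterSummary, fit: MvnFit,
                         n_sims: int = 1000, seed: int | None = 0,
                         sim_cov: np.ndarray | None = None) -> AssignmentMatrix:
    """Repeat the cluster assignment over MVN perturbations of each sample.

    Each replicate draws x*_i ~ MVN(x_i, Σ_sim) — the observed triplet is
    the mean of its own simulation distribution — and assigns x*_i to the
    highest-likelihood cluster.  Σ_sim defaults to the estimated feather
    covariance ``fit.cov`` (pass a diagonal or scaled matrix to explore
    alternatives; the zero matrix reproduces the point assignment in every
    replicate).  Argmax ties break toward the lowest cluster id.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    fit.require_converged()
    if isinstance(records, np.ndarray):
        X = np.asarray(records, dtype=float)
        sample_ids = [f"s{i}" for i in range(len(X))]
    else:
        records = list(records)
        incomplete = [r.sample_id for r in records if not r.complete]
        if incomplete:
            raise ValueError(
                f"incomplete records not allowed in simulation: {incomplete[:5]}")
        X = records_to_matrix(records)
        sample_ids = [r.sample_id for r in records]
    n, d = X.shape
    mus = summary.mean_vectors()
    K = len(summary.cluster_ids)

    # point assignment probabilities
    logf = _log_densities_matrix(X, mus, fit.cov)
    probs = np.exp(logf - logsumexp(logf, axis=-1, keepdims=True))
    modal = summary.cluster_ids[np.argmax(logf, axis=-1)]

    Sigma_sim = fit.cov if sim_cov is None else np.asarray(sim_cov, dtype=float)
    rng = np.random.default_rng(seed)
    if np.allclose(Sigma_sim, 0):
        draws = np.broadcast_to(X, (n_sims, n, d))
    else:
        w, V = np.linalg.eigh(Sigma_sim)
        if w.min() < -1e-10 * max(np.trace(Sigma_sim), 1):
            raise ValueError("simulation covariance is not PSD")
        root = V * np.sqrt(np.clip(w, 0, None))
        draws = X + rng.standard_normal((n_sims, n, d)) @ root.T

    wins = np.argmax(
        _log_densities_matrix(draws.reshape(-1, d), mus, fit.cov), axis=-1
    ).reshape(n_sims, n)

    freq = np.zeros((n, K))
    np.add.at(freq, (np.tile(np.arange(n), n_sims), wins.ravel()), 1)
    freq /= n_sims
    replicate_counts = np.zeros((n_sims, K), dtype=int)
    np.add.at(replicate_counts,
              (np.repeat(np.arange(n_sims), n), wins.ravel()), 1)

    return AssignmentMatrix(sample_ids=sample_ids,
                            cluster_ids=np.asarray(summary.cluster_ids),
                            probs=probs, frequencies=freq,
                            modal_cluster=modal,
                            replicate_counts=replicate_counts,
                            n_sims=n_sims, seed=seed)


def summarize_counts(matrix: AssignmentMatrix) -> PopulationSummary:
    """Mean ± SD number of individuals per cluster across replicates.

    SD uses the sample (n_sims − 1) divisor; with one replicate SD is 0.
    """
    counts = matrix.replicate_counts
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1) if matrix.n_sims > 1 else np.zeros_like(mean)
    return PopulationSummary(cluster_ids=matrix.cluster_ids,
                             mean_counts=mean, sd_counts=sd,
                             n_individuals=matrix.n_individuals,
                             n_sims=matrix.n_sims)
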