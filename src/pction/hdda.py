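"""High-dimensional discriminant analysis with class-specific subspaces.

Each class k is modeled as a Gaussian whose covariance is constrained to a
low-dimensional signal subspace plus isotropic residual noise (the general
"a_kj b_k Q_k d_k" parameterization):

    Sigma_k = Q_k diag(a_k1..a_kd) Q_k^T + b_k (I - Q_k Q_k^T)

with orthonormal basis Q_k (p x d_k), subspace variances a_kj (the top d_k
eigenvalues of the class empirical covariance), shared noise variance b_k
(the mean of the remaining eigenvalues) and intrinsic dimension d_k chosen
per class by Cattell's scree rule on the eigenvalue gaps.  Classification
minimizes the cost

    K_k(x) = ||mu_k - P_k x||^2_{A}  + ||x - P_k x||^2 / b_k
             + sum_j log a_kj + (p - d_k) log b_k - 2 log pi_k

(P_k the affine projector onto the class subspace), which equals
-2 log(pi_k phi(x; mu_k, Sigma_k)) up to the class-independent constant
p log 2 pi; posteriors follow by normalizing exp(-K_k/2) across classes.
The attraction over plain quadratic discriminant analysis is that only
d_k + 1 variances per class must be estimated and inverted, which remains
stable for the many sparsely populated CT classes; with d_k = p - 1 and the
smallest eigenvalue equal to b_k the model reduces to QDA exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "HddaClassModel",
    "HddaModel",
    "select_dimension",
    "fit",
    "cost",
    "posteriors",
]

_FORMAT_VERSION = 1


def select_dimension(eigenvalues: np.ndarray, threshold: float,
                     max_dim: int | None = None) -> int:
    """Cattell scree rule: keep dimensions up to the last 'large' gap.

    With gaps ``delta_j = lambda_j - lambda_{j+1}`` (eigenvalues sorted
    descending), returns the largest j such that
    ``delta_j >= threshold * max(delta)``, bounded to ``[1, p - 1]``.
    Ties on the threshold resolve toward the larger j (more structure kept);
    a flat spectrum (all gaps zero) falls back to d = 1.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 2:
        raise ValueError("scree selection needs at least 2 eigenvalues")
    if np.any(lam < -1e-12):
        raise ValueError("eigenvalues must be non-negative")
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("eigenvalues must be sorted in descending order")
    cap = lam.size - 1 if max_dim is None else min(max_dim, lam.size - 1)
    gaps = -np.diff(lam)  # length p-1, all >= 0
    gmax = gaps.max()
    if gmax <= 0:
        return 1
    passing = np.nonzero(gaps >= threshold * gmax)[0]
    d = int(passing[-1]) + 1 if passing.size else 1
    return max(1, min(d, cap))


@dataclass
class HddaClassModel:
    """Per-class Gaussian subspace model."""

    prior: float
    mean: np.ndarray  # (p,)
    basis: np.ndarray  # (p, d) orthonormal columns
    subspace_var: np.ndarray  # (d,) a_kj, descending, >= noise_var
    noise_var: float  # b_k > 0

    @property
    def d(self) -> int:
        return self.basis.shape[1]

    @property
    def p(self) -> int:
        return self.basis.shape[0]

    def covariance(self) -> np.ndarray:
        """Dense reconstructed covariance (for oracles and serialization checks)."""
        q = self.basis
        return (
            q @ np.diag(self.subspace_var) @ q.T
            + self.noise_var * (np.eye(self.p) - q @ q.T)
        )


@dataclass
class HddaModel:
    """Collection of fitted class models keyed by class label."""

    models: dict[int, HddaClassModel]
    p: int
    threshold: float
    var_floor: float

    @property
    def class_labels(self) -> list[int]:
        return sorted(self.models)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "p": self.p,
            "threshold": self.threshold,
            "var_floor": self.var_floor,
            "classes": {
                str(k): {
                    "prior": m.prior,
                    "mean": m.mean.tolist(),
                    "basis": m.basis.tolist(),
                    "subspace_var": m.subspace_var.tolist(),
                    "noise_var": m.noise_var,
                }
                for k, m in self.models.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HddaModel":
        if d.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {d.get('format_version')}")
        models = {
            int(k): HddaClassModel(
                prior=float(m["prior"]),
                mean=np.asarray(m["mean"], dtype=float),
                basis=np.asarray(m["basis"], dtype=float),
                subspace_var=np.asarray(m["subspace_var"], dtype=float),
                noise_var=float(m["noise_var"]),
            )
            for k, m in d["classes"].items()
        }
        return cls(models=models, p=int(d["p"]), threshold=float(d["threshold"]),
                   var_floor=float(d["var_floor"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "HddaModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _fix_eigenvector_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: first non-negligible component positive."""
    out = vecs.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            out[:, j] = -col
    return out


def fit(
    X: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.2,
    var_floor: float = 1e-6,
) -> HddaModel:
    """Fit one subspace Gaussian per class on scaled features.

    Per class: prior n_k / n, mean, eigendecomposition of the empirical
    (n-denominator) covariance, scree-selected d_k, a_kj the top d_k
    eigenvalues, b_k the mean residual eigenvalue; both floored at
    ``var_floor`` so degenerate classes stay usable.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("fit requires an n x p matrix with p >= 2")
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length must match number of rows")
    n, p = X.shape
    models: dict[int, HddaClassModel] = {}
    for k in np.unique(labels):
        xk = X[labels == k]
        nk = xk.shape[0]
        mu = xk.mean(axis=0)
        cov = np.cov(xk, rowvar=False, ddof=0) if nk > 1 else np.zeros((p, p))
        cov = np.atleast_2d(cov)
        lam, vec = np.linalg.eigh(cov)
        order = np.argsort(lam)[::-1]
        lam = np.maximum(lam[order], 0.0)
        vec = _fix_eigenvector_signs(vec[:, order])
        d = select_dimension(lam, threshold)
        b = lam[d:].mean() if d < p else var_floor
        b = max(b, var_floor)
        a = np.maximum(lam[:d], b)
        models[int(k)] = HddaClassModel(
            prior=nk / n,
            mean=mu,
            basis=vec[:, :d],
            subspace_var=a,
            noise_var=float(b),
        )
    return HddaModel(models=models, p=p, threshold=threshold, var_floor=var_floor)


def cost(model_k: HddaClassModel, x: np.ndarray) -> np.ndarray:
    """Classification cost K_k(x); accepts a single p-vector or an (n, p) array.

    Equals -2 log(pi_k * N(x; mu_k, Sigma_k)) minus the class-independent
    p log 2 pi, with Sigma_k the reconstructed subspace covariance.
    """
    single = np.asarray(x).ndim == 1
    X = np.atleast_2d(np.asarray(x, dtype=float))
    dev = X - model_k.mean
    proj = dev @ model_k.basis  # (n, d)
    quad_sub = (proj**2 / model_k.subspace_var).sum(axis=1)
    resid = (dev**2).sum(axis=1) - (proj**2).sum(axis=1)
    resid = np.maximum(resid, 0.0)
    k = (
        quad_sub
        + resid / model_k.noise_var
        + np.log(model_k.subspace_var).sum()
        + (model_k.p - model_k.d) * np.log(model_k.noise_var)
        - 2.0 * np.log(model_k.prior)
    )
    return k[0] if single else k


def class_costs(model: HddaModel, X: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Cost matrix (n, K) over the model's classes in sorted label order."""
    labels = model.class_labels
    K = np.column_stack([cost(model.models[k], X) for k in labels])
    return K, labels


def posteriors(model: HddaModel, X: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Class posterior probabilities P(C_k | x) for each row of X.

    Computed as softmax(-K_k/2) with max-subtraction for stability; rows sum
    to one over the retained classes.  Returns ``(P, class_labels)``.
    """
    K, labels = class_costs(model, np.atleast_2d(X))
    logw = -0.5 * K
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True), labels
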