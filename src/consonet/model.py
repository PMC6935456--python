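"""Network architecture, feedforward pass, and lasso-penalized objective.

The model is a one-hidden-layer feedforward network augmented with a
gene-wise *consolidation layer*.  Each of the K genes owns M hidden
nodes — one per study in the default vertical-integration setting — and
the ReLU outputs of those nodes are combined into a single consolidation
value per gene through norm-normalized weights::

    a[i,k,m] = sum_p v[k,m,p] * x[i,k,m,p]
    O[i,k,m] = max(a[i,k,m], 0)
    C[i,k]   = sum_m w[k,m] * O[i,k,m] / ||w[k]||_2
    yhat[i]  = beta0 + sum_k beta[k] * C[i,k]
    f[i]     = sigmoid(yhat[i])

Training minimizes the mean binary cross-entropy plus a lasso penalty
``lam * sum_k |beta[k]|`` on the consolidation-to-output weights (the
intercept is unpenalized), so that genes whose consolidation node carries
no class signal are shrunk to ``beta[k] ~ 0`` and can be screened out by
magnitude.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "ArchitectureSpec",
    "OmicsStack",
    "NetworkParams",
    "ForwardCache",
    "Hyperparams",
    "ConformanceError",
    "DegenerateWeightError",
    "forward_hidden",
    "consolidate",
    "predict",
    "forward",
    "penalized_loss",
    "smooth_sign",
]

#: Probabilities are clipped to [PROB_FLOOR, 1 - PROB_FLOOR] before logs.
PROB_FLOOR = 1e-12


class ConformanceError(ValueError):
    """Raised when data and parameter shapes do not agree."""


class DegenerateWeightError(ValueError):
    """Raised when a gene's consolidation weight vector has zero norm."""


@dataclasses.dataclass(frozen=True)
class ArchitectureSpec:
    """Shape of the network.

    Parameters
    ----------
    n_genes : int
        K, the number of genes and hence of consolidation nodes.
    n_hidden : int
        M, hidden nodes per gene; one per study under vertical integration.
    n_features : int
        P, input features feeding each hidden node (1 in the standard
        one-expression-value-per-gene-per-study setting).
    """

    n_genes: int
    n_hidden: int
    n_features: int = 1

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_hidden", "n_features"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")

    @property
    def input_width(self) -> int:
        """Total number of input values per sample."""
        return self.n_genes * self.n_hidden * self.n_features


@dataclasses.dataclass
class OmicsStack:
    """Gene-aligned multi-study data with a binary outcome.

    ``values`` is indexed ``(sample, gene, study, feature)``; all studies
    must share the same samples in the same order and the same gene order
    (vertical integration).
    """

    values: np.ndarray
    labels: np.ndarray
    gene_ids: list[str] = dataclasses.field(default_factory=list)
    study_ids: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 4:
            raise ValueError(
                f"values must be 4-d (sample, gene, study, feature), got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.labels.ndim != 1 or self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels must be a vector with one entry per sample")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        self.labels = self.labels.astype(int)
        if not self.gene_ids:
            self.gene_ids = [f"gene_{k}" for k in range(self.values.shape[1])]
        if not self.study_ids:
            self.study_ids = [f"study_{m}" for m in range(self.values.shape[2])]
        if len(self.gene_ids) != self.values.shape[1]:
            raise ValueError("gene_ids length does not match the gene axis")
        if len(self.study_ids) != self.values.shape[2]:
            raise ValueError("study_ids length does not match the study axis")

    @classmethod
    def from_matrices(
        cls,
        matrices: Sequence[np.ndarray],
        labels: np.ndarray,
        gene_ids: Sequence[str] | None = None,
        study_ids: Sequence[str] | None = None,
    ) -> "OmicsStack":
        """Build a stack from per-study (samples x genes) matrices."""
        mats = [np.asarray(m, dtype=float) for m in matrices]
        if not mats:
            raise ValueError("at least one study matrix is required")
        shape = mats[0].shape
        for i, m in enumerate(mats):
            if m.ndim != 2 or m.shape != shape:
                raise ValueError(
                    f"study {i} has shape {m.shape}, expected {shape}: all studies "
                    "must cover the same samples and genes"
                )
        values = np.stack(mats, axis=2)[..., np.newaxis]
        return cls(
            values=values,
            labels=np.asarray(labels),
            gene_ids=list(gene_ids) if gene_ids is not None else [],
            study_ids=list(study_ids) if study_ids is not None else [],
        )

    @property
    def arch(self) -> ArchitectureSpec:
        _, k, m, p = self.values.shape
        return ArchitectureSpec(n_genes=k, n_hidden=m, n_features=p)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_studies(self) -> int:
        return self.values.shape[2]

    def subset(self, indices: np.ndarray) -> "OmicsStack":
        """Row-subset the stack (used for train/test splits and CV folds)."""
        idx = np.asarray(indices)
        return OmicsStack(
            values=self.values[idx],
            labels=self.labels[idx],
            gene_ids=list(self.gene_ids),
            study_ids=list(self.study_ids),
        )


@dataclasses.dataclass
class NetworkParams:
    """The three weight families of the network.

    ``v`` (K, M, P) input-to-hidden, ``w`` (K, M) hidden-to-consolidation,
    ``beta0`` scalar intercept and ``beta`` (K,) consolidation-to-output.
    Every gene's ``w`` vector must have nonzero Euclidean norm because the
    consolidation step divides by it.
    """

    v: np.ndarray
    w: np.ndarray
    beta0: float
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.beta0 = float(self.beta0)
        if self.v.ndim != 3:
            raise ValueError(f"v must be 3-d (gene, hidden, feature), got shape {self.v.shape}")
        if self.w.ndim != 2 or self.w.shape != self.v.shape[:2]:
            raise ValueError(
                f"w shape {self.w.shape} does not conform to v shape {self.v.shape}"
            )
        if self.beta.ndim != 1 or self.beta.shape[0] != self.v.shape[0]:
            raise ValueError("beta must have one entry per gene")
        for arr, name in ((self.v, "v"), (self.w, "w"), (self.beta, "beta")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
        if not np.isfinite(self.beta0):
            raise ValueError("beta0 is not finite")
        norms = np.linalg.norm(self.w, axis=1)
        if np.any(norms == 0.0):
            k = int(np.flatnonzero(norms == 0.0)[0])
            raise DegenerateWeightError(
                f"consolidation weights for gene index {k} have zero norm"
            )

    @property
    def arch(self) -> ArchitectureSpec:
        k, m, p = self.v.shape
        return ArchitectureSpec(n_genes=k, n_hidden=m, n_features=p)

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.v.copy(), self.w.copy(), self.beta0, self.beta.copy())

    @classmethod
    def unit(cls, arch: ArchitectureSpec) -> "NetworkParams":
        """All-ones v and w with a zero output layer."""
        return cls(
            v=np.ones((arch.n_genes, arch.n_hidden, arch.n_features)),
            w=np.ones((arch.n_genes, arch.n_hidden)),
            beta0=0.0,
            beta=np.zeros(arch.n_genes),
        )


@dataclasses.dataclass
class ForwardCache:
    """Per-sample activations retained for backpropagation.

    ``a`` (N, K, M) pre-activations, ``O`` their ReLU, ``C`` (N, K)
    consolidation values, ``yhat`` the linear outputs and ``f`` the
    predicted probabilities.
    """

    a: np.ndarray
    O: np.ndarray
    C: np.ndarray
    yhat: np.ndarray
    f: np.ndarray


@dataclasses.dataclass
class Hyperparams:
    """Training hyperparameters.

    Parameters
    ----------
    lam : float
        Lasso penalty weight on the output coefficients (>= 0).
    eta : float
        Learning rate of the gradient steps for beta0, w and v.
    s : float
        Scale of the smooth sign approximation; small values make
        z(beta) = 2*sigmoid(beta/s) - 1 close to sign(beta).
    epochs : int
        Maximum number of full feedforward/backpropagation sweeps.
    tol : float
        Stop when the penalized loss changes by less than this per epoch.
    select_eps : float
        |beta_k| threshold above which gene k is called selected.
    ridge_lam : float
        Ridge penalty of the closed-form output-layer initialization.
    exact_w_gradient : bool
        Use the exact derivative of the normalized consolidation (default).
        False reproduces a common approximate form whose second term is
        scaled by ||w||^2 instead of ||w||^3.
    seed : int or None
        Default RNG seed for procedures that need randomness (CV folds).
    """

    lam: float = 0.0
    eta: float = 0.01
    s: float = 1e-3
    epochs: int = 500
    tol: float = 1e-6
    select_eps: float = 1e-2
    ridge_lam: float = 1.0
    exact_w_gradient: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        for name in ("eta", "s", "select_eps", "ridge_lam", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _check_conformance(stack: OmicsStack, params: NetworkParams) -> None:
    if stack.values.shape[1:] != params.v.shape:
        raise ConformanceError(
            f"data (gene, study, feature) shape {stack.values.shape[1:]} does not "
            f"match parameter shape {params.v.shape}"
        )


def forward_hidden(stack: OmicsStack, params: NetworkParams) -> tuple[np.ndarray, np.ndarray]:
    """Input-to-hidden pass: pre-activations ``a`` and ReLU outputs ``O``."""
    _check_conformance(stack, params)
    a = np.einsum("ikmp,kmp->ikm", stack.values, params.v)
    return a, np.maximum(a, 0.0)


def consolidate(O: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Hidden-to-consolidation pass: per-gene norm-normalized combination.

    C[i,k] = sum_m w[k,m] * O[i,k,m] / ||w[k]||_2, which is invariant to
    positive rescaling of each gene's weight vector.
    """
    norms = np.linalg.norm(params.w, axis=1)
    if np.any(norms == 0.0):
        k = int(np.flatnonzero(norms == 0.0)[0])
        raise DegenerateWeightError(
            f"consolidation weights for gene index {k} have zero norm"
        )
    return np.einsum("ikm,km->ik", O, params.w) / norms


def predict(C: np.ndarray, params: NetworkParams) -> tuple[np.ndarray, np.ndarray]:
    """Consolidation-to-output pass: linear score and sigmoid probability."""
    yhat = params.beta0 + C @ params.beta
    return yhat, expit(yhat)


def forward(stack: OmicsStack, params: NetworkParams) -> ForwardCache:
    """Full feedforward pass, retaining all activations for backprop."""
    a, O = forward_hidden(stack, params)
    C = consolidate(O, params)
    yhat, f = predict(C, params)
    return ForwardCache(a=a, O=O, C=C, yhat=yhat, f=f)


def penalized_loss(
    f: np.ndarray, labels: np.ndarray, params: NetworkParams, lam: float
) -> float:
    """Mean binary cross-entropy plus ``lam * sum_k |beta_k|``.

    The intercept is not penalized. Probabilities are clipped away from
    {0, 1} before the logarithms so saturated predictions yield a large
    finite loss instead of infinity.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    y = np.asarray(labels, dtype=float)
    fc = np.clip(np.asarray(f, dtype=float), PROB_FLOOR, 1.0 - PROB_FLOOR)
    ce = -float(np.mean(y * np.log(fc) + (1.0 - y) * np.log(1.0 - fc)))
    return ce + float(lam) * float(np.abs(params.beta).sum())


def smooth_sign(beta: np.ndarray | float, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Smooth sign ``z`` and its derivative ``z'``.

    z(b) = 2*exp(b/s)/(1+exp(b/s)) - 1 and z'(b) = (2/s) * sig * (1-sig)
    with sig = sigmoid(b/s); evaluated through :func:`scipy.special.expit`
    so large |b|/s saturates instead of overflowing. z approximates
    sign(b) for small s while keeping the penalty's curvature defined
    at b = 0 (z'(0) = 1/(2s)).
    """
    if s <= 0:
        raise ValueError("s must be > 0")
    sig = expit(np.asarray(beta, dtype=float) / s)
    return 2.0 * sig - 1.0, (2.0 / s) * sig * (1.0 - sig)
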