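"""Synthetic multi-study expression generator and train/test splitting.

Each study measures the same G genes on the same N samples.  A fixed
subset of *signal* genes carries a class effect: in case samples their
mean is shifted by ``mu`` and they are drawn from MVN(mean, sigma^2 * S)
with S block-exchangeable (correlation ``rho`` within each signal-gene
cluster, 0 between clusters, unit diagonal).  The remaining *nonsignal*
genes are independent noise MVN(0, sigma^2 * I) in every sample.  An
optional number of *random* studies draw ALL genes as pure noise
regardless of class — they emulate an uninformative platform and probe
the selection method's robustness.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.model_selection import train_test_split

from .model import OmicsStack

__all__ = ["SimulationDesign", "signal_covariance", "generate_stack", "split_train_test"]


@dataclasses.dataclass(frozen=True)
class SimulationDesign:
    """Parameters of the synthetic multi-study generator.

    Defaults emulate the benchmark design: 80 genes per study of which 16
    carry signal (two clusters of 8), three studies, N=100 balanced
    samples, case-class mean shift ``mu``=1, within-cluster correlation
    ``rho``=0.5, and a 70/30 train/test split.
    """

    n_signal: int = 16
    n_nonsignal: int = 64
    n_studies: int = 3
    n_random_studies: int = 0
    sigma: float = 0.1
    mu: float = 1.0
    rho: float = 0.5
    n_clusters: int = 2
    n_samples: int = 100
    case_fraction: float = 0.5
    train_fraction: float = 0.7
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_signal < 1 or self.n_nonsignal < 0:
            raise ValueError("need n_signal >= 1 and n_nonsignal >= 0")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if not 0 <= self.n_random_studies < self.n_studies:
            raise ValueError("n_random_studies must lie in [0, n_studies)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")
        if not 1 <= self.n_clusters <= self.n_signal:
            raise ValueError("n_clusters must lie in [1, n_signal]")

    @property
    def n_genes(self) -> int:
        return self.n_signal + self.n_nonsignal

    @property
    def cluster_sizes(self) -> list[int]:
        """Near-equal partition of the signal genes into clusters."""
        base, extra = divmod(self.n_signal, self.n_clusters)
        return [base + (1 if c < extra else 0) for c in range(self.n_clusters)]


def signal_covariance(design: SimulationDesign) -> np.ndarray:
    """Correlation matrix of the signal block: block-diagonal exchangeable.

    Raises before any sampling if ``rho`` makes a block non
    positive-definite (rho must exceed -1/(b-1) for the largest block b).
    """
    blocks = []
    for size in design.cluster_sizes:
        if size > 1 and not (-1.0 / (size - 1) < design.rho < 1.0):
            raise ValueError(
                f"rho={design.rho} is not positive-definite for a cluster of size {size}"
            )
        block = np.full((size, size), design.rho)
        np.fill_diagonal(block, 1.0)
        blocks.append(block)
    out = np.zeros((design.n_signal, design.n_signal))
    start = 0
    for block in blocks:
        stop = start + block.shape[0]
        out[start:stop, start:stop] = block
        start = stop
    return out


def generate_stack(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> tuple[OmicsStack, np.ndarray]:
    """Draw one multi-study dataset.

    Returns the stack and the per-gene ground-truth signal flags (signal
    genes occupy the leading positions).  The last ``n_random_studies``
    studies are all-noise regardless of class.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    corr = signal_covariance(design)  # validates rho before sampling
    chol = np.linalg.cholesky(corr)
    n, g = design.n_samples, design.n_genes

    n_case = int(round(n * design.case_fraction))
    labels = np.zeros(n, dtype=int)
    labels[:n_case] = 1
    rng.shuffle(labels)
    case = labels == 1

    matrices = []
    for m in range(design.n_studies):
        is_random = m >= design.n_studies - design.n_random_studies
        if is_random:
            x = design.sigma * rng.standard_normal((n, g))
        else:
            z = rng.standard_normal((n, design.n_signal))
            signal = design.sigma * (z @ chol.T)
            signal[case] += design.mu
            noise = design.sigma * rng.standard_normal((n, design.n_nonsignal))
            x = np.hstack([signal, noise])
        matrices.append(x)

    cluster_of = np.repeat(
        np.arange(design.n_clusters), design.cluster_sizes
    )
    gene_ids = [f"sig{cluster_of[j] + 1}_g{j + 1}" for j in range(design.n_signal)]
    gene_ids += [f"null_g{j + 1}" for j in range(design.n_nonsignal)]
    study_ids = [
        f"study_{m + 1}" + ("_random" if m >= design.n_studies - design.n_random_studies else "")
        for m in range(design.n_studies)
    ]
    stack = OmicsStack.from_matrices(matrices, labels, gene_ids=gene_ids, study_ids=study_ids)
    truth = np.zeros(g, dtype=bool)
    truth[: design.n_signal] = True
    return stack, truth


def split_train_test(
    stack: OmicsStack,
    design: SimulationDesign,
    seed: int | None = None,
) -> tuple[OmicsStack, OmicsStack]:
    """Stratified random train/test split applied identically to all studies.

    The split is on sample indices, so every study keeps the same samples
    on the same side.  If a class ends up absent from either side the
    split is redrawn (up to 100 times) before erroring.
    """
    if stack.n_samples < 10:
        raise ValueError("at least 10 samples are required to split")
    if seed is None:
        seed = design.seed
    indices = np.arange(stack.n_samples)
    base = 0 if seed is None else int(seed)
    for attempt in range(100):
        train_idx, test_idx = train_test_split(
            indices,
            train_size=design.train_fraction,
            stratify=stack.labels,
            random_state=(base + attempt) % 2**31,
        )
        train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
        if (
            len(np.unique(stack.labels[train_idx])) == 2
            and len(np.unique(stack.labels[test_idx])) == 2
        ):
            return stack.subset(train_idx), stack.subset(test_idx)
    raise RuntimeError("could not produce a split with both classes on both sides")
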