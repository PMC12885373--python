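"""Generative model for PCR-biased amplicon sequencing experiments.

Counts are simulated from the multinomial logistic-normal hierarchy

    Y_n   ~ Multinomial(depth_n, pi_n)
    pi_n  = phi_inverse(eta_n)
    eta_n ~ Normal(Lambda @ X_n, Sigma)

where the coefficient matrix ``Lambda = [alpha^(1) ... alpha^(C) beta]``
holds one baseline (cycle-0) log-ratio composition per community and a
shared per-cycle bias column ``beta = Psi log b`` derived from per-taxon
amplification efficiencies ``b`` in [1, 2].  The per-sample mean
``alpha + x_n beta`` is the exponential amplification model expressed in
log-ratio coordinates: after ``x`` cycles an observed two-template ratio is
``(a1/a2) * (b1/b2)**x``.

:func:`mock_community_study` bundles the whole calibration design used
throughout the package: D taxa, several communities, replicates sequenced at
different PCR cycle numbers so the per-cycle bias is identifiable as a slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .compositions import (
    ContrastMatrix,
    make_contrast_matrix,
    phi_inverse,
    validate_efficiencies,
)

__all__ = [
    "CountMatrix",
    "DesignMatrix",
    "SimulationTruth",
    "SyntheticStudy",
    "expected_ratio",
    "efficiencies_to_beta",
    "latent_eta",
    "latent_compositions",
    "make_design",
    "mock_community_study",
    "simulate_counts",
    "simulate_efficiencies",
    "simulate_tree",
]


@dataclass
class CountMatrix:
    """A taxa-by-samples table of sequencing read counts."""

    counts: np.ndarray  # (D, N) nonnegative integers
    taxon_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        y = np.asarray(self.counts)
        if y.ndim != 2:
            raise ValueError("counts must be a 2-D taxa-by-samples array")
        if not np.issubdtype(y.dtype, np.integer):
            yf = np.asarray(y, dtype=float)
            if np.any(yf % 1 != 0):
                raise ValueError("counts must be integer-valued")
            y = yf.astype(np.int64)
        if np.any(y < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(y.sum(axis=0) <= 0):
            bad = [self.sample_ids[i] for i in np.flatnonzero(y.sum(axis=0) <= 0)]
            raise ValueError(f"every sample needs at least one read; empty: {bad}")
        if len(self.taxon_ids) != y.shape[0] or len(self.sample_ids) != y.shape[1]:
            raise ValueError("taxon/sample label lengths must match the count matrix")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.counts = y.astype(np.int64)
        self.taxon_ids = list(self.taxon_ids)
        self.sample_ids = list(self.sample_ids)

    @property
    def D(self) -> int:
        return self.counts.shape[0]

    @property
    def N(self) -> int:
        return self.counts.shape[1]

    @property
    def depths(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def compositions(self, pseudo_count: float | None = None) -> np.ndarray:
        """Column-normalized relative abundances, (D, N).

        Counts of zero make the plain proportions leave the open simplex;
        pass ``pseudo_count`` (0.5 is the conventional choice) to add a
        constant before normalizing so every part is strictly positive.
        """
        y = self.counts.astype(float)
        if pseudo_count is not None:
            if pseudo_count <= 0:
                raise ValueError("pseudo_count must be positive")
            y = y + pseudo_count
        elif np.any(y == 0):
            raise ValueError(
                "count matrix contains zeros; pass pseudo_count to obtain "
                "strictly positive compositions"
            )
        return y / y.sum(axis=0, keepdims=True)


@dataclass
class DesignMatrix:
    """Covariates-by-samples design: community one-hot rows plus a cycle row."""

    X: np.ndarray  # (p, N)
    covariate_names: list[str]
    cycle_row: int

    def __post_init__(self) -> None:
        x = np.asarray(self.X, dtype=float)
        if x.ndim != 2:
            raise ValueError("design matrix must be 2-D (covariates x samples)")
        p = x.shape[0]
        if len(self.covariate_names) != p:
            raise ValueError("covariate_names length must equal the number of rows")
        if not 0 <= self.cycle_row < p:
            raise ValueError("cycle_row out of range")
        ind = np.delete(x, self.cycle_row, axis=0)
        if not np.all((ind == 0.0) | (ind == 1.0)):
            raise ValueError("community indicator entries must be 0/1")
        if not np.all(ind.sum(axis=0) == 1.0):
            raise ValueError("each sample must belong to exactly one community")
        cyc = x[self.cycle_row]
        if np.any(cyc < 0) or np.any(cyc % 1 != 0):
            raise ValueError("cycle covariate must be a nonnegative integer")
        self.X = x
        self.covariate_names = list(self.covariate_names)

    @property
    def p(self) -> int:
        return self.X.shape[0]

    @property
    def N(self) -> int:
        return self.X.shape[1]

    @property
    def communities(self) -> list[str]:
        return [n for i, n in enumerate(self.covariate_names) if i != self.cycle_row]

    @property
    def cycles(self) -> np.ndarray:
        return self.X[self.cycle_row].astype(int)

    def community_of(self, n: int) -> str:
        rows = [i for i in range(self.p) if i != self.cycle_row]
        hot = [i for i in rows if self.X[i, n] == 1.0]
        return self.covariate_names[hot[0]]


def make_design(communities, cycles) -> DesignMatrix:
    """Build the one-hot-plus-cycle design from per-sample labels.

    Communities are ordered by first appearance; the cycle covariate is the
    last row.
    """
    communities = list(communities)
    cycles = np.asarray(list(cycles), dtype=float)
    if len(communities) == 0:
        raise ValueError("need at least one sample")
    if len(communities) != cycles.size:
        raise ValueError("communities and cycles must have the same length")
    order: list[str] = []
    for c in communities:
        if c not in order:
            order.append(c)
    n = len(communities)
    X = np.zeros((len(order) + 1, n))
    for j, c in enumerate(communities):
        X[order.index(c), j] = 1.0
    X[-1] = cycles
    return DesignMatrix(X, covariate_names=order + ["cycles"], cycle_row=len(order))


@dataclass
class SimulationTruth:
    """Ground-truth parameters behind a simulated dataset."""

    lambda_true: np.ndarray  # (D-1, p)
    sigma_true: np.ndarray  # (D-1, D-1)
    seed: int
    depths: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambda_true, dtype=float)
        sig = np.asarray(self.sigma_true, dtype=float)
        if lam.ndim != 2 or sig.shape != (lam.shape[0], lam.shape[0]):
            raise ValueError("lambda_true (D-1, p) and sigma_true (D-1, D-1) must be consistent")
        if np.max(np.abs(sig - sig.T)) > 1e-10:
            raise ValueError("sigma_true must be symmetric")
        if np.min(np.linalg.eigvalsh((sig + sig.T) / 2)) < -1e-10:
            raise ValueError("sigma_true must be positive semi-definite")
        d = np.asarray(self.depths)
        if np.any(d < 1) or np.any(np.asarray(d, dtype=float) % 1 != 0):
            raise ValueError("sequencing depths must be integers >= 1")
        self.lambda_true = lam
        self.sigma_true = (sig + sig.T) / 2
        self.depths = np.asarray(d, dtype=np.int64)


def expected_ratio(a1: float, a2: float, b1: float, b2: float, x: float) -> float:
    """Expected observed two-template ratio after ``x`` PCR cycles.

    Exponential amplification: ``(a1/a2) * (b1/b2)**x`` with per-cycle
    efficiencies ``b1, b2`` in [1, 2].
    """
    for name, v in (("a1", a1), ("a2", a2), ("b1", b1), ("b2", b2)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive, got {v!r}")
    if b1 > 2 or b2 > 2 or b1 < 1 or b2 < 1:
        raise ValueError("efficiencies must lie in [1, 2]")
    if x < 0:
        raise ValueError("cycle count must be nonnegative")
    return (a1 / a2) * (b1 / b2) ** x


def efficiencies_to_beta(b, psi: ContrastMatrix) -> np.ndarray:
    """Per-cycle log-ratio bias vector ``beta = Psi log b``."""
    eff = validate_efficiencies(b)
    if eff.size != psi.D:
        raise ValueError(f"efficiency vector has {eff.size} taxa but basis expects {psi.D}")
    return psi.matrix @ np.log(eff)


def latent_eta(lambda_: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Noise-free latent log-ratio means ``Lambda @ X``, (D-1, N)."""
    lam = np.asarray(lambda_, dtype=float)
    if lam.shape[1] != design.p:
        raise ValueError("lambda and design have inconsistent covariate dimension")
    return lam @ design.X


def latent_compositions(lambda_: np.ndarray, design: DesignMatrix, psi: ContrastMatrix) -> np.ndarray:
    """Noise-free per-sample compositions implied by ``Lambda @ X``, (D, N)."""
    eta = latent_eta(lambda_, design)
    return np.column_stack([phi_inverse(eta[:, n], psi) for n in range(design.N)])


def simulate_counts(
    truth: SimulationTruth,
    design: DesignMatrix,
    psi: ContrastMatrix,
    noise_free: bool = False,
    taxon_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> CountMatrix:
    """Draw a count table from the multinomial logistic-normal hierarchy.

    Randomness flows from ``truth.seed`` through one child generator per
    sample (numpy ``SeedSequence.spawn``), so re-simulating a prefix of the
    samples reproduces them exactly.  With ``noise_free`` the latent
    log-ratios are set to their means ``Lambda @ X_n`` (no logistic-normal
    noise); multinomial sampling still applies.
    """
    r, p = truth.lambda_true.shape
    if p != design.p:
        raise ValueError("truth and design have inconsistent covariate dimension")
    if psi.D != r + 1:
        raise ValueError("basis dimension inconsistent with lambda_true")
    if truth.depths.size != design.N:
        raise ValueError("depths length must equal the number of samples")
    D, N = r + 1, design.N
    if taxon_ids is None:
        taxon_ids = [f"taxon_{i + 1:02d}" for i in range(D)]
    if sample_ids is None:
        sample_ids = [f"sample_{i + 1:03d}" for i in range(N)]

    mean = latent_eta(truth.lambda_true, design)
    chol = None
    if not noise_free and np.any(truth.sigma_true != 0.0):
        # PSD but possibly singular: use eigen square root
        w, v = np.linalg.eigh(truth.sigma_true)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    streams = np.random.SeedSequence(truth.seed).spawn(N)
    counts = np.zeros((D, N), dtype=np.int64)
    for n in range(N):
        rng = np.random.default_rng(streams[n])
        eta_n = mean[:, n].copy()
        if chol is not None:
            eta_n += chol @ rng.standard_normal(r)
        pi = phi_inverse(eta_n, psi)
        counts[:, n] = rng.multinomial(int(truth.depths[n]), pi / pi.sum())
    return CountMatrix(counts, taxon_ids, sample_ids)


def simulate_efficiencies(D: int, seed: int, spread: float = 0.3) -> np.ndarray:
    """Draw per-taxon amplification efficiencies uniformly in [2-spread, 2].

    Efficiencies near 2 (small spread) give small per-cycle log-ratio biases
    that accumulate into visible distortion over tens of cycles.
    """
    if D < 2:
        raise ValueError("need at least 2 taxa")
    if not 0 < spread <= 1:
        raise ValueError("spread must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    return np.clip(rng.uniform(2.0 - spread, 2.0, size=D), 1.0, 2.0)


def simulate_tree(taxon_ids, seed: int, mean_branch_length: float = 0.1) -> dendropy.Tree:
    """Random rooted bifurcating tree with exponential branch lengths.

    Topology is built by repeatedly joining uniformly chosen subtree pairs;
    tips carry ``taxon_ids`` verbatim.
    """
    labels = list(taxon_ids)
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa for a tree")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxon ids")
    rng = np.random.default_rng(seed)
    frags = [f"'{lab}'" for lab in labels]
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        right = frags.pop(j)
        left = frags.pop(i)
        bl, br = rng.exponential(mean_branch_length, size=2)
        merged = f"({left}:{bl:.10g},{right}:{br:.10g})"
        frags.append(merged)
    newick = frags[0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


@dataclass
class SyntheticStudy:
    """A complete synthetic calibration experiment with its ground truth."""

    counts: CountMatrix
    design: DesignMatrix
    truth: SimulationTruth
    psi: ContrastMatrix
    efficiencies: np.ndarray
    beta_true: np.ndarray
    alpha_true: dict[str, np.ndarray]
    tree: dendropy.Tree
    metadata: pd.DataFrame


def mock_community_study(
    seed: int = 0,
    n_taxa: int = 10,
    n_communities: int = 10,
    cycles: tuple[int, ...] = (20, 28, 35),
    depth: int = 10_000,
    sigma_scale: float = 0.1,
    efficiency_spread: float = 0.3,
    alpha_scale: float = 1.5,
    basis: str = "alr",
    noise_free: bool = False,
) -> SyntheticStudy:
    """Simulate a mock-community calibration study.

    Defaults emulate a ten-isolate mock-community experiment: ten
    communities, each sequenced as three replicates at distinct PCR cycle
    numbers (20, 28, 35), 10,000 reads per replicate, per-taxon
    amplification efficiencies drawn near 2 so relative biases are small per
    cycle, baseline community log-ratios drawn iid Normal(0, alpha_scale^2)
    to produce the uneven, one-or-two-dominant-taxa profiles typical of
    constructed mock communities, and isotropic logistic-normal replicate
    noise ``Sigma = sigma_scale * I``.
    """
    rng0 = np.random.default_rng(seed)
    s_eff, s_alpha, s_tree, s_counts = (int(v) for v in rng0.integers(2**31 - 1, size=4))

    psi = make_contrast_matrix(basis, n_taxa)
    eff = simulate_efficiencies(n_taxa, seed=s_eff, spread=efficiency_spread)
    beta = efficiencies_to_beta(eff, psi)

    rng_a = np.random.default_rng(s_alpha)
    names = [f"community_{i + 1:02d}" for i in range(n_communities)]
    alphas = {name: alpha_scale * rng_a.standard_normal(n_taxa - 1) for name in names}

    community_labels = [name for name in names for _ in cycles]
    cycle_labels = [c for _ in names for c in cycles]
    design = make_design(community_labels, cycle_labels)

    lam = np.column_stack([alphas[name] for name in names] + [beta])
    truth = SimulationTruth(
        lambda_true=lam,
        sigma_true=sigma_scale * np.eye(n_taxa - 1),
        seed=s_counts,
        depths=np.full(design.N, depth, dtype=np.int64),
    )
    taxon_ids = [f"taxon_{i + 1:02d}" for i in range(n_taxa)]
    counts = simulate_counts(truth, design, psi, noise_free=noise_free, taxon_ids=taxon_ids)
    tree = simulate_tree(taxon_ids, seed=s_tree)
    metadata = pd.DataFrame(
        {
            "sample_id": counts.sample_ids,
            "community": community_labels,
            "cycles": cycle_labels,
        }
    )
    return SyntheticStudy(
        counts=counts,
        design=design,
        truth=truth,
        psi=psi,
        efficiencies=eff,
        beta_true=beta,
        alpha_true=alphas,
        tree=tree,
        metadata=metadata,
    )
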