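"""Synthetic benchmark generators: multivariate-t clusters with sparse precisions.

The binary-cluster benchmarks draw n = 2 x 50 samples over p = 100 genes.
The first ``p1 = 10`` genes are *informative*: within each cluster they follow
a 10-variate Student's t with cluster mean ``mu_k`` and a (possibly sparse,
possibly cluster-specific) inverse scale matrix.  The remaining 90 *noise*
genes are i.i.d. univariate standard t with the same degrees of freedom, for
every cluster, and are independent of the informative block by construction.
Gene columns are standardized before return, as the estimators expect.

Four structural set-ups:

1. ten mean-shifted genes, identity precision in both clusters;
2. eight mean-shifted genes plus two null-mean genes tied to them through a
   shared banded sparse precision (single attachment edges);
3. five mean-shifted genes plus five null-mean genes whose sparse precisions
   differ between the clusters (random symmetric insertions in the null-mean
   section);
4. as 3, but the random edges span the whole informative section, coupling
   the discriminative genes and so adding correlated noise to the mean
   signal.

The multi-cluster fixture appends three "thin-tailed" (nu = 100) clusters of
15 samples each, with disjoint blocks of ten +/-2 mean-shifted genes and
diagonal scale, on top of a set-up-4 pair of fat-tailed clusters; p grows to
130 so that the 90 noise genes are retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, standardize

__all__ = [
    "SimulationTruth",
    "sample_mvt",
    "make_sparse_precision",
    "generate_setup",
    "generate_multicluster",
]

_DEFAULT_SHIFT = 1.5
# per-gene mean shifts between the two clusters, expressed on the
# standardized (post gene-scaling) axis the model parameters live on;
# set-up 4 is slightly weaker ("more noise based on the mean")
_SETUP_SHIFTS = {1: 1.5, 2: 1.5, 3: 1.55, 4: 1.45}
_EDGE_VALUE = -0.8
_MIN_EIG = 0.1


@dataclass
class SimulationTruth:
    """Generating parameters and ground truth for scoring a simulated dataset."""

    labels: np.ndarray
    mu_true: np.ndarray          # K x p (on the raw, pre-standardization scale)
    omega_true: np.ndarray       # K x p x p
    informative_genes: tuple
    mean_discriminative_genes: tuple
    nu: float
    seed: int
    setup: str = ""

    def __post_init__(self):
        inf = set(self.informative_genes)
        if not inf >= set(self.mean_discriminative_genes):
            raise ValueError("mean-discriminative genes must be informative")
        for k in range(self.omega_true.shape[0]):
            if np.linalg.eigvalsh(self.omega_true[k]).min() <= 0:
                raise ValueError("true precision must be positive definite")

    @property
    def noise_genes(self) -> tuple:
        p = self.mu_true.shape[1]
        return tuple(j for j in range(p) if j not in set(self.informative_genes))

    def to_json(self) -> str:
        return json.dumps(
            dict(
                labels=self.labels.tolist(),
                mu_true=self.mu_true.tolist(),
                omega_true=self.omega_true.tolist(),
                informative_genes=list(self.informative_genes),
                mean_discriminative_genes=list(self.mean_discriminative_genes),
                nu=self.nu,
                seed=self.seed,
                setup=self.setup,
            )
        )

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        return cls(
            labels=np.asarray(d["labels"], dtype=int),
            mu_true=np.asarray(d["mu_true"], dtype=float),
            omega_true=np.asarray(d["omega_true"], dtype=float),
            informative_genes=tuple(d["informative_genes"]),
            mean_discriminative_genes=tuple(d["mean_discriminative_genes"]),
            nu=float(d["nu"]),
            seed=int(d["seed"]),
            setup=d.get("setup", ""),
        )


def sample_mvt(n: int, mu, omega, nu: float, seed) -> np.ndarray:
    """Draw n samples from a multivariate t with inverse scale ``omega``.

    Uses the scale-mixture construction x = mu + z / sqrt(g / nu) with
    z ~ N(0, omega^{-1}) and g ~ chi-square(nu); requires nu > 2 so the
    covariance nu/(nu-2) * omega^{-1} exists.
    """
    if nu <= 2:
        raise ValueError("degrees of freedom must exceed 2")
    rng = np.random.default_rng(seed)
    mu = np.asarray(mu, dtype=float)
    omega = np.asarray(omega, dtype=float)
    L = np.linalg.cholesky(omega)
    y = rng.standard_normal((n, mu.size))
    # z = L^{-T} y has covariance (L L^T)^{-1} = omega^{-1}
    z = np.linalg.solve(L.T, y.T).T
    g = rng.chisquare(nu, size=n)
    return mu + z / np.sqrt(g / nu)[:, None]


def _to_generating_scale(shift: float, nu: float) -> float:
    """Convert a standardized-scale shift to the raw generating scale.

    The model's means live on the per-gene standardized axis.  A balanced
    two-cluster gene with raw between-cluster shift s (in noise-sd units)
    has total variance 1 + s^2/4, so the standardized shift is
    s* = s / sqrt(1 + s^2/4); this inverts that map (requires s* < 2) and
    multiplies by the t noise scale sqrt(nu/(nu-2)) so the signal-to-noise
    ratio does not depend on the tail weight.
    """
    if shift >= 2.0:
        raise ValueError("standardized shift of a balanced two-cluster gene is < 2")
    raw = shift / np.sqrt(1.0 - shift**2 / 4.0)
    return raw * np.sqrt(nu / (nu - 2.0))


def _pd_rescale(A: np.ndarray, min_eig: float = _MIN_EIG) -> np.ndarray:
    """Add the smallest multiple of I giving min eigenvalue >= min_eig,
    then rescale symmetrically to unit diagonal."""
    w = np.linalg.eigvalsh(A).min()
    if w < min_eig:
        A = A + (min_eig - w) * np.eye(A.shape[0])
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    return 0.5 * (A + A.T)


def make_sparse_precision(p: int, n_offdiag_nonzeros: int, section=None, seed=0,
                          value: float = _EDGE_VALUE) -> np.ndarray:
    """Random sparse PD precision with exactly the requested off-diagonal support.

    Starts from the identity, inserts ``n_offdiag_nonzeros`` off-diagonal
    entries (an even count: symmetric pairs) of magnitude ``|value|`` with
    random signs at random positions within ``section`` (an index range,
    default all genes), enforces positive definiteness by adding a multiple
    of the identity, and rescales to unit diagonal.
    """
    if n_offdiag_nonzeros % 2:
        raise ValueError("n_offdiag_nonzeros must be even (symmetric insertion)")
    rng = np.random.default_rng(seed)
    idx = np.arange(p) if section is None else np.asarray(list(section), dtype=int)
    m = idx.size
    n_pairs = n_offdiag_nonzeros // 2
    avail = m * (m - 1) // 2
    if n_pairs > avail:
        raise ValueError(
            f"section of {m} genes has only {avail} pairs; {n_pairs} requested"
        )
    A = np.eye(p)
    iu, ju = np.triu_indices(m, k=1)
    chosen = rng.choice(avail, size=n_pairs, replace=False)
    for c in chosen:
        i, j = idx[iu[c]], idx[ju[c]]
        v = value * rng.choice([-1.0, 1.0])
        A[i, j] = A[j, i] = v
    return _pd_rescale(A)


def _setup2_precision() -> np.ndarray:
    """Shared sparse precision for set-up 2: band over the eight
    discriminative genes plus single edges attaching genes 8 and 9."""
    A = np.eye(10)
    for j in range(7):  # weak chain 0-1-...-7 among the discriminative genes
        A[j, j + 1] = A[j + 1, j] = -0.1
    A[0, 8] = A[8, 0] = _EDGE_VALUE
    A[1, 9] = A[9, 1] = _EDGE_VALUE
    return _pd_rescale(A)


def _assemble(blocks, nus, noise_p, noise_nu, seed, setup_name, p1_list, mu_list,
              omega_list, informative, discriminative):
    """Stack cluster blocks with i.i.d. t noise genes and standardize."""
    seed_scalar = seed[0] if isinstance(seed, (list, tuple)) else seed
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    for k, (block, nu_k) in enumerate(zip(blocks, nus)):
        n_k = block.shape[0]
        noise = rng.standard_t(noise_nu, size=(n_k, noise_p))
        rows.append(np.hstack([block, noise]))
        labels.extend([k] * n_k)
    values = np.vstack(rows)
    labels = np.asarray(labels, dtype=int)
    p = values.shape[1]
    K = len(blocks)
    mu_true = np.zeros((K, p))
    omega_true = np.stack([np.eye(p) for _ in range(K)])
    for k in range(K):
        p1 = p1_list[k]
        mu_true[k, :p1] = mu_list[k]
        omega_true[k, :p1, :p1] = omega_list[k]
    X = standardize(ExpressionMatrix(values=values))
    truth = SimulationTruth(
        labels=labels, mu_true=mu_true, omega_true=omega_true,
        informative_genes=tuple(informative),
        mean_discriminative_genes=tuple(discriminative),
        nu=float(nus[0]), seed=int(seed_scalar), setup=setup_name,
    )
    return X, truth


def generate_setup(setup_id: int, nu: float = 20.0, seed=0, n_per_cluster: int = 50,
                   p: int = 100, p1: int = 10, shift: float | None = None):
    """Generate one binary-cluster benchmark dataset.

    Returns (standardized ExpressionMatrix, SimulationTruth).  Cluster 1 has
    zero means; cluster 2's mean-discriminative genes are shifted by
    ``shift`` (per-set-up default when omitted).
    """
    if setup_id not in (1, 2, 3, 4):
        raise ValueError("setup_id must be 1, 2, 3 or 4")
    if shift is None:
        shift = _SETUP_SHIFTS[setup_id]
    shift = _to_generating_scale(shift, nu)
    seed = int(seed)
    rng = np.random.default_rng([seed, setup_id])
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]

    if setup_id == 1:
        n_disc = p1
        omega1 = omega2 = np.eye(p1)
    elif setup_id == 2:
        n_disc = 8
        omega1 = omega2 = _setup2_precision()
    else:
        # 3 and 4: cluster-specific structure on the five null-mean genes;
        # set-up 4 differs in its (weaker) mean shifts
        n_disc = 5
        omega1 = make_sparse_precision(p1, 6, section=range(5, p1), seed=sub[0])
        omega2 = make_sparse_precision(p1, 6, section=range(5, p1), seed=sub[1])

    mu1 = np.zeros(p1)
    mu2 = np.zeros(p1)
    mu2[:n_disc] = shift
    b1 = sample_mvt(n_per_cluster, mu1, omega1, nu, seed=sub[2])
    b2 = sample_mvt(n_per_cluster, mu2, omega2, nu, seed=sub[3])
    return _assemble(
        blocks=[b1, b2], nus=[nu, nu], noise_p=p - p1, noise_nu=nu,
        seed=[seed, setup_id, 17], setup_name=f"setup{setup_id}",
        p1_list=[p1, p1], mu_list=[mu1, mu2], omega_list=[omega1, omega2],
        informative=range(p1), discriminative=range(n_disc),
    )


def generate_multicluster(nu: float = 6.0, seed=0, n_fat: int = 50, n_thin: int = 15,
                          p1: int = 10, n_noise: int = 90, thin_shift: float = 4.0,
                          thin_nu: float = 100.0):
    """Five-cluster fixture: a set-up-4 fat-tailed pair plus three thin clusters.

    Clusters 1-2 reuse the set-up-4 generator settings over the first ``p1``
    genes.  Clusters 3-5 have ``n_thin`` samples each, diagonal scale,
    ``thin_nu`` degrees of freedom, and disjoint blocks of ten genes shifted
    by alternating +/- ``thin_shift``.  Noise genes are i.i.d. t with the fat
    ``nu`` for every cluster; p = p1 + 30 + n_noise.
    """
    seed = int(seed)
    rng = np.random.default_rng([seed, 5])
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=8)]
    block_size = 10
    p_inf = p1 + 3 * block_size

    omega_fat = [
        make_sparse_precision(p1, 6, section=range(5, p1), seed=sub[0]),
        make_sparse_precision(p1, 6, section=range(5, p1), seed=sub[1]),
    ]
    mu_fat = [np.zeros(p_inf), np.zeros(p_inf)]
    mu_fat[1][:5] = _to_generating_scale(_SETUP_SHIFTS[4], nu)

    # thin-cluster blocks in raw noise-sd units (unbalanced 15/145 clusters)
    signs = np.where(np.arange(block_size) % 2 == 0, 1.0, -1.0)
    mu_thin = []
    for t in range(3):
        m = np.zeros(p_inf)
        m[p1 + t * block_size: p1 + (t + 1) * block_size] = (
            thin_shift * np.sqrt(thin_nu / (thin_nu - 2.0)) * signs
        )
        mu_thin.append(m)

    blocks = []
    omegas_full = []
    for k in range(2):
        fat = sample_mvt(n_fat, mu_fat[k][:p1], omega_fat[k], nu, seed=sub[2 + k])
        rest = np.random.default_rng(sub[4 + k]).standard_t(nu, size=(n_fat, 3 * block_size))
        blocks.append(np.hstack([fat, rest]))
        om = np.eye(p_inf)
        om[:p1, :p1] = omega_fat[k]
        omegas_full.append(om)
    for t in range(3):
        thin = sample_mvt(
            n_thin, mu_thin[t], np.eye(p_inf), thin_nu,
            seed=int(np.random.default_rng([sub[6], t]).integers(0, 2**31 - 1)),
        )
        blocks.append(thin)
        omegas_full.append(np.eye(p_inf))

    discriminative = list(range(5)) + list(range(p1, p_inf))
    return _assemble(
        blocks=blocks, nus=[nu, nu, thin_nu, thin_nu, thin_nu],
        noise_p=n_noise, noise_nu=nu, seed=[seed, 5, 17],
        setup_name="multicluster",
        p1_list=[p_inf] * 5,
        mu_list=mu_fat + mu_thin,
        omega_list=omegas_full,
        informative=range(p_inf),
        discriminative=discriminative,
    )
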