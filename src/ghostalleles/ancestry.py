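"""Supervised two-reference ancestry estimation and PCA.

The ancestry model: each of a diploid focal individual's two gene copies
at locus l descends from reference population A with probability q (else
B), and carries the ALT allele with that population's frequency p_A,l or
p_B,l. Copies are independent across and within loci, so the dosage is
Binomial(2, m_l) with m_l = q p_A,l + (1 - q) p_B,l. q is estimated by
maximum likelihood via EM on per-copy ancestry responsibilities — a
deterministic supervised counterpart to Bayesian assignment tests trained
on two reference groups. Reference frequencies are clamped away from 0
and 1 so alleles unobserved in a reference (the ghost-allele case) cannot
produce infinite log-likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class AncestryEstimate:
    focal: str
    q_a: float
    log_likelihood: float
    n_loci: int
    n_iter: int
    converged: bool
    identifiable: bool = True
    warnings: list[str] | None = None

    @property
    def q_b(self) -> float:
        return 1.0 - self.q_a


def _loglik(q: float, dos: np.ndarray, p_a: np.ndarray, p_b: np.ndarray) -> float:
    m = q * p_a + (1.0 - q) * p_b
    return float(np.sum(dos * np.log(m) + (2 - dos) * np.log1p(-m)))


def supervised_q(
    focal_dosages: np.ndarray,
    freqs_A: np.ndarray,
    freqs_B: np.ndarray,
    epsilon: float = 0.001,
    max_iter: int = 500,
    tol: float = 1e-6,
    focal_name: str = "focal",
) -> AncestryEstimate:
    """Maximum-likelihood ancestry fraction q toward reference A.

    EM iterates per-copy responsibilities from the deterministic start
    q = 0.5; convergence when |dq| < ``tol``. Loci with a missing focal
    call or an undefined reference frequency are dropped. If the two
    references are indistinguishable at every used locus the likelihood
    is flat; q = 0.5 is returned with ``identifiable=False``.
    """
    dos = np.asarray(focal_dosages)
    p_a = np.asarray(freqs_A, dtype=float)
    p_b = np.asarray(freqs_B, dtype=float)
    if not (dos.shape == p_a.shape == p_b.shape):
        raise ValueError("dosages and frequency vectors must align")
    use = (dos != MISSING) & np.isfinite(p_a) & np.isfinite(p_b)
    dos = dos[use].astype(float)
    p_a = np.clip(p_a[use], epsilon, 1.0 - epsilon)
    p_b = np.clip(p_b[use], epsilon, 1.0 - epsilon)
    n_loci = int(dos.size)
    warnings: list[str] = []
    if n_loci == 0:
        raise ValueError("no usable loci for ancestry estimation")
    if n_loci < 50:
        warnings.append(f"only {n_loci} informative loci; estimate may be unstable")
    if np.allclose(p_a, p_b):
        return AncestryEstimate(
            focal=focal_name,
            q_a=0.5,
            log_likelihood=_loglik(0.5, dos, p_a, p_b),
            n_loci=n_loci,
            n_iter=0,
            converged=True,
            identifiable=False,
            warnings=warnings or None,
        )

    # per-copy sufficient statistics: dos ALT copies and (2 - dos) REF copies
    q = 0.5
    prev_ll = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        # responsibility that a copy carrying ALT (resp. REF) came from A
        r_alt = q * p_a / (q * p_a + (1.0 - q) * p_b)
        r_ref = q * (1.0 - p_a) / (q * (1.0 - p_a) + (1.0 - q) * (1.0 - p_b))
        q_new = float(np.sum(dos * r_alt + (2.0 - dos) * r_ref) / (2.0 * n_loci))
        ll = _loglik(q_new, dos, p_a, p_b)
        if ll + 1e-9 < prev_ll:  # EM guarantee; numerical slack only
            raise RuntimeError("EM log-likelihood decreased")
        dq = abs(q_new - q)
        q, prev_ll = q_new, ll
        if dq < tol:
            converged = True
            break
    return AncestryEstimate(
        focal=focal_name,
        q_a=q,
        log_likelihood=prev_ll,
        n_loci=n_loci,
        n_iter=it,
        converged=converged,
        warnings=warnings or None,
    )


@dataclass
class PCAResult:
    samples: list[str]
    scores: np.ndarray  # (n_samples, n_components)
    explained_variance_ratio: np.ndarray

    def score(self, sample: str, component: int = 0) -> float:
        return float(self.scores[self.samples.index(sample), component])


def pca_projection(
    G: GenotypeMatrix, n_components: int = 10, scale: bool = True
) -> PCAResult:
    """PCA of the dosage matrix with genotype-aware centering.

    Missing dosages are mean-imputed per site; sites are centered at 2p
    and optionally scaled by sqrt(2p(1-p)) (unit variance under
    Hardy-Weinberg). Component signs are fixed by forcing each
    component's largest-magnitude site loading positive.
    """
    if G.n_samples < 2 or G.n_sites < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 sites")
    X = G.calls.astype(float)
    V = X != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(V, X, 0).sum(axis=0) / np.maximum(2 * V.sum(axis=0), 1)
    mean = 2.0 * p
    X = np.where(V, X, mean[None, :])
    X = X - mean[None, :]
    if scale:
        sd = np.sqrt(2.0 * p * (1.0 - p))
        keep = sd > 0
        X = X[:, keep] / sd[keep][None, :]
    if not (X != 0).any():
        raise ValueError("zero-variance genotype matrix")
    n_components = min(n_components, G.n_samples - 1, X.shape[1])
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = float((S**2).sum())
    scores = U[:, :n_components] * S[:n_components]
    evr = (S[:n_components] ** 2) / total_var if total_var > 0 else S[:n_components] * 0
    for c in range(n_components):
        lead = np.argmax(np.abs(Vt[c]))
        if Vt[c, lead] < 0:
            scores[:, c] *= -1.0
    return PCAResult(samples=list(G.samples), scores=scores, explained_variance_ratio=evr)
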