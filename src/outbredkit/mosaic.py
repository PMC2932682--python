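"""Probabilistic founder-mosaic reconstruction.

Each outbred genome is modeled as a mosaic of segments inherited from a
fixed panel of S homozygous inbred founder strains.  A hidden Markov model
over founder pairs runs along each chromosome: the hidden state at a
marker is the unordered pair of founders carried by the two haplotypes;
transitions factorize per haplotype (each haplotype independently switches
ancestry across an interval with probability 1 - exp(-G * d / 100) for
genetic distance d cM and G breeding generations, a switch landing on any
founder uniformly); emissions compare the observed diploid genotype with
the pair's implied genotype under a per-allele error rate epsilon.

Computation runs in the ordered-pair space (S^2 states) where the
transition kernel is a Kronecker product, so one forward or backward step
costs two S x S matrix multiplications; posteriors are reported over the
S(S+1)/2 unordered pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, FounderPanel, GenotypeMatrix, MarkerMap

logger = logging.getLogger(__name__)


@dataclass
class MosaicModel:
    """HMM parameters: founder panel, expected generations since founding G,
    per-allele genotyping error epsilon, and a uniform genetic map scale."""

    founders: FounderPanel
    G: float = 30.0
    genotype_error: float = 0.01
    cM_per_Mb: float = 0.5

    def __post_init__(self) -> None:
        if self.founders.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if not 0 <= self.genotype_error <= 0.2:
            raise ValueError("genotype_error must be in [0, 0.2]")
        if self.G < 1:
            raise ValueError("G must be >= 1")


@dataclass
class MosaicPosterior:
    """Per-individual posterior over unordered founder pairs at each marker.

    ``probs`` has shape (n_markers, n_pairs) with rows summing to 1;
    ``pairs`` lists the (i, j) founder index pairs (i <= j).
    """

    sample: str
    founder_names: list[str]
    pairs: list[tuple[int, int]]
    probs: np.ndarray
    log_likelihood: float

    def founder_dosages(self) -> np.ndarray:
        """(n_markers, S) expected count of haplotypes from each founder."""
        S = len(self.founder_names)
        out = np.zeros((self.probs.shape[0], S))
        for k, (i, j) in enumerate(self.pairs):
            out[:, i] += self.probs[:, k]
            out[:, j] += self.probs[:, k]
        return out


@dataclass
class FounderContribution:
    colony_id: str
    founder_names: list[str]
    fractions: np.ndarray


def interval_recombination(
    markers: MarkerMap, G: float, cM_per_Mb: float = 0.5
) -> np.ndarray:
    """Per-interval probability that a haplotype switches ancestry.

    Interval i spans markers i -> i+1 on the same chromosome; the genetic
    distance is d = bp * cM_per_Mb / 1e6 and the switch probability
    1 - exp(-G d / 100), i.e. at least one ancestry junction accumulated
    over G generations on a uniform map.  Chromosome boundaries get switch
    probability 1 (independent restart).
    """
    pos = markers.positions_bp
    chroms = markers.chromosomes
    n = len(markers)
    out = np.zeros(max(n - 1, 0))
    for i in range(n - 1):
        if chroms[i] != chroms[i + 1]:
            out[i] = 1.0
            continue
        d_cm = (pos[i + 1] - pos[i]) * cM_per_Mb / 1e6
        out[i] = 1.0 - np.exp(-G * d_cm / 100.0)
    return out


def emission_probability(call: int, allele_b_i: float, allele_b_j: float, eps: float) -> float:
    """P(observed dosage | founder pair) under per-allele error ``eps``.

    ``allele_b_*`` are the founder haplotypes' probabilities of carrying
    allele B (0/1 for clean homozygous calls, 0.5 when uninformative).
    Missing observations return 1 for every state.
    """
    if call == MISSING:
        return 1.0
    pb1 = allele_b_i * (1 - eps) + (1 - allele_b_i) * eps
    pb2 = allele_b_j * (1 - eps) + (1 - allele_b_j) * eps
    if call == 0:
        return (1 - pb1) * (1 - pb2)
    if call == 2:
        return pb1 * pb2
    return pb1 * (1 - pb2) + (1 - pb1) * pb2


def _emission_matrix(calls: np.ndarray, fb: np.ndarray, eps: float) -> np.ndarray:
    """(n_markers, S, S) emissions for one individual in ordered-pair space.

    ``fb`` is the founder x marker allele-B probability matrix.
    """
    pb = fb * (1 - eps) + (1 - fb) * eps  # S x m
    m = calls.shape[0]
    S = fb.shape[0]
    E = np.ones((m, S, S))
    p1 = pb.T[:, :, None]  # m x S x 1
    p2 = pb.T[:, None, :]  # m x 1 x S
    hom_a = (1 - p1) * (1 - p2)
    hom_b = p1 * p2
    het = p1 * (1 - p2) + (1 - p1) * p2
    obs0 = calls == 0
    obs1 = calls == 1
    obs2 = calls == 2
    E[obs0] = hom_a[obs0]
    E[obs1] = het[obs1]
    E[obs2] = hom_b[obs2]
    return E


def forward_backward(
    calls: np.ndarray, model: MosaicModel, sample: str = ""
) -> MosaicPosterior:
    """Exact scaled forward-backward posterior over founder pairs.

    ``calls`` is one individual's dosage vector aligned to the founder
    panel's marker map.
    """
    fp = model.founders
    fb = fp.allele_b_prob()
    S = fp.n_founders
    mmap = fp.genotypes.markers
    m = len(mmap)
    if calls.shape != (m,):
        raise ValueError("calls not aligned to founder markers")
    r = interval_recombination(mmap, model.G, model.cM_per_Mb)
    E = _emission_matrix(calls, fb, model.genotype_error)

    # single-haplotype transition: stay w.p. (1-r) + r/S, move w.p. r/S
    alpha = np.full((S, S), 1.0 / (S * S))
    alphas = np.empty((m, S, S))
    scales = np.empty(m)
    a = alpha * E[0]
    scales[0] = a.sum()
    if scales[0] <= 0:
        raise FloatingPointError("forward underflow at marker 0")
    a /= scales[0]
    alphas[0] = a
    for t in range(1, m):
        rt = r[t - 1]
        stay = 1.0 - rt + rt / S
        move = rt / S
        # per-haplotype kernel applied on both axes; T = stay*I + move*(J - I)
        # acts as T @ v = (stay - move) * v + move * sum(v)
        row_sum = a.sum(axis=0, keepdims=True)
        a1 = (stay - move) * a + move * row_sum
        col_sum = a1.sum(axis=1, keepdims=True)
        a2 = (stay - move) * a1 + move * col_sum
        a = a2 * E[t]
        scales[t] = a.sum()
        if scales[t] <= 0:
            raise FloatingPointError(f"forward underflow at marker {t}")
        a /= scales[t]
        alphas[t] = a

    b = np.ones((S, S))
    post = np.empty((m, S, S))
    post[m - 1] = alphas[m - 1] * b
    for t in range(m - 2, -1, -1):
        rt = r[t]
        stay = 1.0 - rt + rt / S
        move = rt / S
        be = b * E[t + 1]
        row_sum = be.sum(axis=0, keepdims=True)
        b1 = (stay - move) * be + move * row_sum
        col_sum = b1.sum(axis=1, keepdims=True)
        b = ((stay - move) * b1 + move * col_sum) / scales[t + 1]
        post[t] = alphas[t] * b
    post /= post.sum(axis=(1, 2), keepdims=True)

    pairs = [(i, j) for i in range(S) for j in range(i, S)]
    probs = np.empty((m, len(pairs)))
    for k, (i, j) in enumerate(pairs):
        probs[:, k] = post[:, i, j] if i == j else post[:, i, j] + post[:, j, i]
    ll = float(np.log(scales).sum())
    return MosaicPosterior(sample, list(fp.founder_names), pairs, probs, ll)


def backward_log_likelihood(calls: np.ndarray, model: MosaicModel) -> float:
    """Model log-likelihood computed from the backward recursion alone
    (cross-check against the forward scaling product)."""
    fp = model.founders
    fb = fp.allele_b_prob()
    S = fp.n_founders
    mmap = fp.genotypes.markers
    m = len(mmap)
    r = interval_recombination(mmap, model.G, model.cM_per_Mb)
    E = _emission_matrix(calls, fb, model.genotype_error)
    b = np.ones((S, S))
    log_scale = 0.0
    for t in range(m - 2, -1, -1):
        rt = r[t]
        stay = 1.0 - rt + rt / S
        move = rt / S
        be = b * E[t + 1]
        row_sum = be.sum(axis=0, keepdims=True)
        b1 = (stay - move) * be + move * row_sum
        col_sum = b1.sum(axis=1, keepdims=True)
        b = (stay - move) * b1 + move * col_sum
        s = b.sum()
        b /= s
        log_scale += np.log(s)
    val = (np.full((S, S), 1.0 / (S * S)) * E[0] * b).sum()
    return float(np.log(val) + log_scale)


def enumerate_path_posterior(
    calls: np.ndarray, model: MosaicModel
) -> tuple[list[tuple[int, int]], np.ndarray, float]:
    """Brute-force posterior by summing over every ordered-state path.

    Exponential in the number of markers; usable only on tiny instances
    (serves as the independent oracle for :func:`forward_backward`).
    """
    fp = model.founders
    fb = fp.allele_b_prob()
    S = fp.n_founders
    mmap = fp.genotypes.markers
    m = len(mmap)
    r = interval_recombination(mmap, model.G, model.cM_per_Mb)
    E = _emission_matrix(calls, fb, model.genotype_error)
    states = list(itertools.product(range(S), repeat=2))

    def trans(rt: float, x: int, y: int) -> float:
        return (1.0 - rt + rt / S) if x == y else rt / S

    post = np.zeros((m, S, S))
    total = 0.0
    for path in itertools.product(states, repeat=m):
        p = (1.0 / (S * S)) * E[0][path[0]]
        for t in range(1, m):
            a, bb = path[t - 1], path[t]
            p *= trans(r[t - 1], a[0], bb[0]) * trans(r[t - 1], a[1], bb[1]) * E[t][bb]
        total += p
        for t in range(m):
            post[t][path[t]] += p
    post /= total
    pairs = [(i, j) for i in range(S) for j in range(i, S)]
    probs = np.empty((m, len(pairs)))
    for k, (i, j) in enumerate(pairs):
        probs[:, k] = post[:, i, j] if i == j else post[:, i, j] + post[:, j, i]
    return pairs, probs, float(np.log(total))


def mosaic_posteriors(
    g: GenotypeMatrix, model: MosaicModel
) -> list[MosaicPosterior]:
    """Forward-backward posteriors for every sample in ``g`` (markers must
    already be aligned to the founder panel)."""
    if not np.array_equal(g.markers.marker_ids, model.founders.genotypes.markers.marker_ids):
        raise ValueError("genotypes not aligned to founder panel; run align_to_founders")
    return [
        forward_backward(g.calls[i], model, sample=g.samples[i])
        for i in range(g.n_samples)
    ]


def _interval_weights_bp(markers: MarkerMap) -> np.ndarray:
    """Per-marker bp weights: half the span to each same-chromosome
    neighbour (markers represent the surrounding interval)."""
    pos = markers.positions_bp.astype(float)
    chroms = markers.chromosomes
    n = len(markers)
    w = np.zeros(n)
    for i in range(n):
        left = pos[i] - pos[i - 1] if i > 0 and chroms[i - 1] == chroms[i] else 0.0
        right = pos[i + 1] - pos[i] if i < n - 1 and chroms[i + 1] == chroms[i] else 0.0
        w[i] = (left + right) / 2.0
    if w.sum() == 0:
        w[:] = 1.0
    return w


def founder_contributions(
    posteriors: list[MosaicPosterior], markers: MarkerMap, colony_id: str = ""
) -> FounderContribution:
    """Expected genome fraction per founder, averaged over individuals and
    markers with interval-length (bp) weights.  Fractions sum to 1."""
    if not posteriors:
        raise ValueError("no posteriors")
    w = _interval_weights_bp(markers)
    w = w / w.sum()
    S = len(posteriors[0].founder_names)
    acc = np.zeros(S)
    for p in posteriors:
        dos = p.founder_dosages() / 2.0  # n_markers x S, rows sum to 1
        acc += w @ dos
    acc /= len(posteriors)
    acc /= acc.sum()
    return FounderContribution(colony_id, list(posteriors[0].founder_names), acc)
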