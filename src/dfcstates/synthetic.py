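"""Synthetic multi-subject cohorts with Markov-switching covariance structure.

Each subject's component signals are drawn volume-by-volume from the
multivariate normal of a hidden connectivity state; hidden states evolve by a
row-stochastic Markov chain.  Group effects are injected by perturbing the
patient group's chain, giving a known ground truth for occupancy and
transition comparisons downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .prep import ComponentTimecourses
from .subdomains import DEFAULT_BLOCKS

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticGroundTruth",
    "make_state_covariances",
    "make_markov_matrix",
    "simulate_cohort",
    "simulate_motion",
]

_ACTIVE_LOAD_RANGE = (0.35, 0.6)   # squared loading of active-metacluster components
_INACTIVE_LOAD = 0.01              # squared loading (opposite sign) of inactive components
_ACTIVE_EXTRA_RANGE = (0.1, 0.3)   # extra within-block coherence, active subdomains
_INACTIVE_EXTRA_RANGE = (0.0, 0.05)  # residual within-block coherence, inactive subdomains
_MIN_EIGENVALUE = 0.05     # floor applied when repairing indefiniteness


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    """Independent per-subject stream; stable when the cohort grows.

    Derived as ``SeedSequence(seed, spawn_key=(subject_index,))`` so subject i
    always receives the same stream for a given master seed, regardless of how
    many other subjects are simulated.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject_index,)))


def _even_blocks(n_components: int, n_blocks: int = 7) -> tuple[int, ...]:
    n_blocks = min(n_blocks, n_components)
    base, extra = divmod(n_components, n_blocks)
    return tuple(base + (1 if i < extra else 0) for i in range(n_blocks))


def _shrink_to_pd(matrices: list[np.ndarray]) -> list[np.ndarray]:
    """Blend all matrices toward the identity with one shared factor.

    ``(1 - a) R + a I`` preserves every off-diagonal sign pattern (and all
    between-state pattern correlations) exactly, unlike eigenvalue clipping;
    ``a`` is the smallest value raising every eigenvalue to the floor.
    """
    lam_min = min(float(np.linalg.eigvalsh(r).min()) for r in matrices)
    if lam_min >= _MIN_EIGENVALUE:
        return [r.copy() for r in matrices]
    a = (_MIN_EIGENVALUE - lam_min) / (1.0 - lam_min)
    return [(1.0 - a) * r + a * np.eye(r.shape[0]) for r in matrices]


def make_state_covariances(
    n_components: int,
    k_true: int,
    block_structure: tuple[int, ...] | None = None,
    separation: float = 0.9,
    seed: int = 0,
    max_tries: int = 200,
) -> list[np.ndarray]:
    """Build ``k_true`` distinct positive-definite correlation matrices.

    Each state *activates* a metacluster of blocks (subdomains): active
    components share a strong positive loading, inactive components carry a
    small opposite-sign loading, so correlations are high within the active
    metacluster, weakly negative between active and inactive subdomains, and
    active subdomains are internally far more coherent than inactive ones.
    The rank-one-plus-block-diagonal construction is positive definite by
    construction.  State 1 activates a balanced half of the blocks and state 2
    the complementary half, so at separation 1 their vectorized upper
    triangles are negatively correlated; further states activate random
    subsets accepted only if every pairwise vectorized correlation stays
    below ~0.35.  ``separation`` blends each state toward the common average
    structure: ``(1 - separation) * base + separation * state``, keeping
    positive definiteness and making between-state similarity monotone.

    Parameters
    ----------
    block_structure
        Component counts per block; must sum to ``n_components``.  Defaults to
        the seven subdomain sizes (2, 4, 17, 7, 5, 9, 9) when they fit, else
        a near-even 7-way split.
    separation
        In ``(0, 1]``; larger values push the states further apart.
    """
    if not (0 < separation <= 1):
        raise ValueError("separation must be in (0, 1]")
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    if block_structure is None:
        block_structure = DEFAULT_BLOCKS if sum(DEFAULT_BLOCKS) == n_components else _even_blocks(n_components)
    block_structure = tuple(int(b) for b in block_structure)
    if sum(block_structure) != n_components:
        raise ValueError(
            f"block structure {block_structure} sums to {sum(block_structure)}, "
            f"expected {n_components}"
        )
    n_blocks = len(block_structure)
    labels = np.repeat(np.arange(n_blocks), block_structure)
    same_block = labels[:, None] == labels[None, :]
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_components, k=1)

    def build(active: np.ndarray) -> np.ndarray:
        """active: bool per block; full-separation correlation matrix.

        Loading levels are drawn per block so that states sharing an active
        subdomain still differ there - keeps the states near-equidistant in
        feature space instead of hierarchically grouped.
        """
        load = np.where(active, rng.uniform(*_ACTIVE_LOAD_RANGE, n_blocks), _INACTIVE_LOAD)
        sign = np.where(active, 1.0, -1.0)
        u = sign[labels] * np.sqrt(load[labels])
        r = np.outer(u, u)
        extra = np.where(
            active,
            rng.uniform(*_ACTIVE_EXTRA_RANGE, n_blocks),
            rng.uniform(*_INACTIVE_EXTRA_RANGE, n_blocks),
        )
        r[same_block] += extra[labels[np.where(same_block)[0]]]
        np.fill_diagonal(r, 1.0)
        return r

    def balanced_split() -> np.ndarray:
        """Boolean mask whose two sides hold near-equal component counts."""
        mask = np.empty(n_blocks, dtype=bool)
        load = {True: 0, False: 0}
        for b in np.argsort(block_structure)[::-1]:
            side = load[True] <= load[False]
            mask[b] = side
            load[side] += block_structure[b]
        return mask

    full: list[np.ndarray] = []
    vecs: list[np.ndarray] = []
    for state in range(k_true):
        if state == 0:
            r = build(balanced_split())
        elif state == 1 and k_true == 2:
            # complementary metacluster: disjoint strong-correlation support,
            # hence negatively correlated vectorized upper triangles.  Only for
            # a two-state design: with more states this hierarchical geometry
            # would dominate the finer state structure.
            r = build(~balanced_split())
        else:
            # draw metacluster masks keeping the states near-equidistant:
            # accept at the tightest feasible pairwise-correlation threshold
            r = None
            sizes = np.asarray(block_structure)
            for threshold in (0.15, 0.25, 0.35):
                for _ in range(max_tries):
                    mask = rng.random(n_blocks) < 0.5
                    # skip lopsided metaclusters: too-small active sets have a
                    # weak signature, near-global ones overlap every state
                    frac = sizes[mask].sum() / n_components
                    if not (0.25 <= frac <= 0.75):
                        continue
                    cand = build(mask)
                    v = cand[iu]
                    if all(abs(np.corrcoef(v, w)[0, 1]) < threshold for w in vecs):
                        r = cand
                        break
                if r is not None:
                    break
            if r is None:
                raise RuntimeError(
                    f"could not draw a sufficiently distinct covariance for state {state + 1}"
                )
        full.append(r)
        vecs.append(r[iu])
    if separation < 1.0:
        base = sum(full) / len(full) if k_true > 1 else np.eye(n_components)
        full = [(1.0 - separation) * base + separation * r for r in full]
    return _shrink_to_pd(full)


def make_markov_matrix(k_true: int, mean_dwell_target: float) -> np.ndarray:
    """Uniform-off-diagonal chain with self-transition 1 - 1/mean_dwell."""
    if mean_dwell_target <= 1:
        raise ValueError("mean_dwell_target must exceed 1 volume")
    if k_true == 1:
        return np.ones((1, 1))
    stay = 1.0 - 1.0 / mean_dwell_target
    leave = (1.0 - stay) / (k_true - 1)
    m = np.full((k_true, k_true), leave)
    np.fill_diagonal(m, stay)
    return m


@dataclass
class SyntheticCohortConfig:
    """Generator configuration; defaults mirror the target acquisition
    (225 volumes, TR 2 s, 53 components, 17 subjects per group)."""

    n_per_group: int = 17
    n_components: int = 53
    n_volumes: int = 225
    tr_seconds: float = 2.0
    k_true: int = 4
    state_covariances: list[np.ndarray] | None = None
    markov_matrix: np.ndarray | None = None
    mean_dwell_target: float = 40.0
    noise_sd: float = 0.3
    group_effect: float = 0.0
    separation: float = 0.9
    motion_amplitude: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_volumes <= 3 + 22 + 25:
            raise ValueError("n_volumes must exceed 50 (discard + both window lengths)")
        if self.state_covariances is None:
            self.state_covariances = make_state_covariances(
                self.n_components, self.k_true, separation=self.separation, seed=self.seed
            )
        if len(self.state_covariances) != self.k_true:
            raise ValueError("need one covariance per latent state")
        for s, cov in enumerate(self.state_covariances):
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (self.n_components, self.n_components):
                raise ValueError(f"state {s + 1}: covariance shape {cov.shape} != C x C")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"state {s + 1}: covariance not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"state {s + 1}: covariance not positive definite")
            self.state_covariances[s] = cov
        if self.markov_matrix is None:
            self.markov_matrix = make_markov_matrix(self.k_true, self.mean_dwell_target)
        self.markov_matrix = np.asarray(self.markov_matrix, dtype=float)
        if self.markov_matrix.shape != (self.k_true, self.k_true):
            raise ValueError("markov_matrix must be k_true x k_true")
        if not np.allclose(self.markov_matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("markov_matrix rows must sum to 1")
        if (self.markov_matrix < 0).any():
            raise ValueError("markov_matrix entries must be non-negative")


@dataclass
class SyntheticGroundTruth:
    """Hidden truth of a simulated cohort: per-subject state paths (1-based
    labels), per-subject motion traces, and the generating configuration."""

    config: SyntheticCohortConfig
    state_sequences: dict[str, np.ndarray] = field(default_factory=dict)
    motion: dict[str, np.ndarray] = field(default_factory=dict)
    clinical: dict[str, dict[str, float]] = field(default_factory=dict)


def _group_markov(config: SyntheticCohortConfig, group: str) -> np.ndarray:
    """Patient chain with occupancy of state 1 boosted by ``group_effect``."""
    m = config.markov_matrix.copy()
    if group == "patient" and config.group_effect != 0 and config.k_true > 1:
        m[:, 0] *= 1.0 + config.group_effect
        m /= m.sum(axis=1, keepdims=True)
    return m


def _simulate_chain(rng: np.random.Generator, markov: np.ndarray, n_steps: int) -> np.ndarray:
    k = markov.shape[0]
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.integers(k)
    cum = markov.cumsum(axis=1)
    draws = rng.random(n_steps - 1)
    for t in range(1, n_steps):
        states[t] = np.searchsorted(cum[states[t - 1]], draws[t - 1], side="right")
    return states


def simulate_motion(n_volumes: int, amplitude: float = 0.02, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Smooth random-walk motion traces (6 x T): mm translations, rad rotations.

    ``amplitude`` scales the per-volume translation step in mm; rotation steps
    are scaled so their framewise-displacement contribution (on a 50 mm
    sphere) matches the translations.  ``amplitude=0`` yields all zeros.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = rng.normal(size=(6, n_volumes)) * amplitude
    steps[3:] /= 50.0  # rotations in radians, FD-equivalent on a 50 mm sphere
    kernel = np.ones(5) / 5.0
    smooth = np.apply_along_axis(lambda s: np.convolve(s, kernel, mode="same"), 1, steps)
    walk = np.cumsum(smooth, axis=1)
    walk -= walk[:, :1]
    return walk


def _clinical_scores(rng: np.random.Generator, group: str) -> dict[str, float]:
    if group != "patient":
        return {"cgi": float("nan"), "bdi": float("nan"), "bai": float("nan")}
    return {
        "cgi": float(rng.integers(3, 7)),
        "bdi": float(rng.integers(4, 30)),
        "bai": float(rng.integers(4, 30)),
    }


def simulate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[ComponentTimecourses], SyntheticGroundTruth]:
    """Draw a two-group cohort of component time courses.

    Returns the subjects (controls first, then patients, ids ``C01.., P01..``)
    and the ground truth holding each subject's hidden 1-based state path,
    motion trace, and clinical scores.  Bit-for-bit reproducible for a fixed
    config and seed.
    """
    chols = [np.linalg.cholesky(cov) for cov in config.state_covariances]
    truth = SyntheticGroundTruth(config=config)
    subjects: list[ComponentTimecourses] = []
    idx = 0
    for group, prefix in (("control", "C"), ("patient", "P")):
        markov = _group_markov(config, group)
        for i in range(config.n_per_group):
            rng = _subject_rng(config.seed, idx)
            sid = f"{prefix}{i + 1:02d}"
            path = _simulate_chain(rng, markov, config.n_volumes)
            z = rng.normal(size=(config.n_volumes, config.n_components))
            data = np.empty_like(z)
            for s in range(config.k_true):
                rows = path == s
                if rows.any():
                    data[rows] = z[rows] @ chols[s].T
            if config.noise_sd > 0:
                data += config.noise_sd * rng.normal(size=data.shape)
            subjects.append(
                ComponentTimecourses(subject_id=sid, group=group, data=data, tr_seconds=config.tr_seconds)
            )
            truth.state_sequences[sid] = path + 1
            truth.motion[sid] = simulate_motion(config.n_volumes, config.motion_amplitude, rng)
            truth.clinical[sid] = _clinical_scores(rng, group)
            idx += 1
    return subjects, truth
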