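"""Synthetic multi-subject, multi-session connectome cohorts.

The generator emulates the statistical structure that fingerprinting and
behavioural prediction exploit in resting-state cohorts, using an additive
subject/session Gaussian model per edge:

    x[j, s, i] = base(i) + u_j(i) + eps[j, s](i)

* ``base(i)`` is a block baseline (higher within than between resting-state
  networks),
* ``u_j(i)`` is a subject component drawn once per subject and therefore
  stable across sessions — its SD is ``sigma_identity`` on a small planted
  set of identity edges, ``sigma_behaviour`` on a planted behaviour set and
  ``sigma_background`` elsewhere,
* ``eps[j, s](i)`` is independent session noise with SD ``sigma_session``.

A behavioural score is a weighted sum of the subject components on the
behaviour edges plus noise; the components on those edges share a latent
trait (``behaviour_coupling``), so each behaviour edge individually carries
a detectable correlation with the score — the mechanism connectome-based
prediction requires — while identity edges vary idiosyncratically and carry
no score information.  The default SD ordering
(background < behaviour < identity) reproduces the empirical picture that
highly discriminatory edges are the most variable across participants and
predictive edges sit at intermediate variability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import (
    ConnectomeSet,
    Parcellation,
    devectorize,
    edge_node_pairs,
    n_edges,
    vectorize_upper,
)

__all__ = [
    "CohortParams",
    "GroundTruth",
    "Cohort",
    "make_parcellation",
    "simulate_cohort",
    "simulate_timeseries",
    "write_cohort",
    "read_cohort",
]


@dataclass
class CohortParams:
    """Parameters of the synthetic cohort generator.

    All SDs are in (z-scored) connectivity units.  The defaults are the
    package's reference study conditions: 40 subjects, a 60-node / 6-network
    spherical parcellation, 1% planted identity edges (SD 0.5), 1% planted
    behaviour edges (SD 0.1) coupled to a single behavioural score, low
    background variability (SD 0.05) and session noise (SD 0.075) sized so
    that behaviour edges are clearly less session-stable than identity
    edges — the property that keeps them out of the top differential-power
    percentile while remaining individually detectable by prediction.
    """

    n_subjects: int = 40
    n_nodes: int = 60
    n_networks: int = 6
    n_sessions: int = 2
    n_runs_per_session: int = 2
    f_identity: float = 0.01
    f_behaviour: float = 0.01
    set_overlap: float = 0.0
    sigma_identity: float = 0.5
    sigma_behaviour: float = 0.1
    sigma_background: float = 0.05
    sigma_session: float = 0.075
    beta_snr: float = 3.0
    behaviour_coupling: float = 0.5
    base_within: float = 0.4
    base_between: float = 0.1
    n_behaviours: int = 1
    behaviour_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sigma_identity",
            "sigma_behaviour",
            "sigma_background",
            "sigma_session",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("f_identity", "f_behaviour", "set_overlap", "behaviour_coupling"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if self.n_networks > self.n_nodes:
            raise ValueError("n_networks cannot exceed n_nodes")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort, kept for recovery tests."""

    identity_edges: np.ndarray
    behaviour_edges: np.ndarray
    behaviour_weights: np.ndarray  # length E, nonzero only on behaviour_edges
    true_scores_noiseless: np.ndarray  # (n_subjects,)


@dataclass
class Cohort:
    params: CohortParams
    parcellation: Parcellation
    connectomes: ConnectomeSet
    behaviours: pd.DataFrame  # index: subject id, one column per score
    truth: GroundTruth
    session_targets: np.ndarray = field(repr=False, default=None)  # (S, n_sessions, E)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-angle lattice)."""
    k = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_parcellation(n_nodes: int, n_networks: int, seed: int) -> Parcellation:
    """Spherical synthetic parcellation with spatially contiguous networks.

    Node centroids sit on a quasi-uniform (golden-angle) lattice on the unit
    sphere.  Network labels come from ``n_networks`` seed directions (a
    second, randomly rotated lattice): each node joins the network of its
    nearest seed direction, so networks form contiguous caps — the property a
    spin permutation null needs.  The rotation is redrawn until every network
    is non-empty.
    """
    if not 1 <= n_networks <= n_nodes:
        raise ValueError("need n_nodes >= n_networks >= 1")
    centroids = _fibonacci_sphere(n_nodes)
    rng = np.random.default_rng(seed)
    seeds = _fibonacci_sphere(n_networks)
    for _ in range(100):
        rot = _random_rotation(rng)
        labels = np.argmax(centroids @ (seeds @ rot.T).T, axis=1)
        if np.unique(labels).size == n_networks:
            break
    else:  # pragma: no cover - lattice geometry makes this unreachable in practice
        raise RuntimeError("could not place non-empty networks")
    return Parcellation(
        node_ids=[f"node{k:03d}" for k in range(n_nodes)],
        networks=np.array([f"net{l + 1}" for l in labels]),
        centroids=centroids,
    )


def _plant_edge_sets(
    E: int, params: CohortParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n_id = int(round(params.f_identity * E))
    n_beh = int(round(params.f_behaviour * E))
    identity = rng.choice(E, size=n_id, replace=False)
    n_shared = min(int(round(params.set_overlap * n_beh)), n_id, n_beh)
    shared = rng.choice(identity, size=n_shared, replace=False)
    pool = np.setdiff1d(np.arange(E), identity, assume_unique=False)
    fresh = rng.choice(pool, size=n_beh - n_shared, replace=False)
    behaviour = np.sort(np.concatenate([shared, fresh]).astype(int))
    return np.sort(identity.astype(int)), behaviour


def simulate_cohort(params: CohortParams | None = None, **kwargs) -> Cohort:
    """Draw a full synthetic cohort (connectomes, behaviours, ground truth).

    Keyword arguments override fields of ``params`` (or of a default
    :class:`CohortParams` when none is given).  All randomness derives from
    ``params.seed``; identical parameters give bit-identical cohorts.
    """
    if params is None:
        params = CohortParams(**kwargs)
    elif kwargs:
        params = CohortParams(**{**asdict(params), **kwargs})
    p = params
    if (
        p.n_subjects > 1
        and p.sigma_identity == p.sigma_behaviour == p.sigma_background == 0.0
    ):
        warnings.warn(
            "all subject-level SDs are zero: subjects are exchangeable and "
            "identification is at chance",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(p.seed)
    parc = make_parcellation(p.n_nodes, p.n_networks, seed=p.seed)
    E = n_edges(p.n_nodes)

    ii, jj = edge_node_pairs(p.n_nodes)
    within = parc.networks[ii] == parc.networks[jj]
    base = np.where(within, p.base_within, p.base_between)

    identity, behaviour = _plant_edge_sets(E, p, rng)
    sigma = np.full(E, p.sigma_background)
    sigma[behaviour] = p.sigma_behaviour
    sigma[identity] = p.sigma_identity  # overlap edges keep the identity SD

    S, K = p.n_subjects, behaviour.size
    # subject components; behaviour edges share a latent trait g_j
    u = rng.standard_normal((S, E)) * sigma
    signs = rng.choice([-1.0, 1.0], size=K)
    lam = p.behaviour_coupling
    if K:
        g = rng.standard_normal(S)
        idio = rng.standard_normal((S, K))
        u[:, behaviour] = sigma[behaviour] * (
            np.sqrt(lam) * np.outer(g, signs) + np.sqrt(1.0 - lam) * idio
        )

    weights = np.zeros(E)
    weights[behaviour] = signs
    noiseless = u[:, behaviour] @ signs if K else np.zeros(S)
    # population SD of the noiseless score, for the SNR-controlled noise
    sig_b = sigma[behaviour]
    var_signal = lam * float(np.sum(np.abs(signs) * sig_b)) ** 2 + (1.0 - lam) * float(
        np.sum(signs**2 * sig_b**2)
    )
    if np.isinf(p.beta_snr) or var_signal == 0.0:
        noise_sd = 0.0
    else:
        noise_sd = np.sqrt(var_signal) / p.beta_snr
    y = noiseless + noise_sd * rng.standard_normal(S)

    subjects = [f"sub{j:03d}" for j in range(S)]
    beh = {"score1": y}
    if p.n_behaviours > 1:
        y_std = (y - y.mean()) / y.std() if y.std() > 0 else np.zeros(S)
        for b in range(2, p.n_behaviours + 1):
            extra = rng.standard_normal(S)
            beh[f"score{b}"] = p.behaviour_corr * y_std + np.sqrt(
                max(0.0, 1.0 - p.behaviour_corr**2)
            ) * extra
    behaviours = pd.DataFrame(beh, index=pd.Index(subjects, name="subject_id"))

    data = np.empty((S, p.n_sessions, E))
    for s in range(p.n_sessions):
        data[:, s, :] = base + u + p.sigma_session * rng.standard_normal((S, E))

    cset = ConnectomeSet(
        subjects=subjects,
        sessions=[f"ses{s + 1}" for s in range(p.n_sessions)],
        n_nodes=p.n_nodes,
        data=data,
    )
    truth = GroundTruth(
        identity_edges=identity,
        behaviour_edges=behaviour,
        behaviour_weights=weights,
        true_scores_noiseless=noiseless,
    )
    return Cohort(
        params=p,
        parcellation=parc,
        connectomes=cset,
        behaviours=behaviours,
        truth=truth,
        session_targets=data,
    )


def _nearest_pd_correlation(target: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at a small positive floor, then the matrix is
    rescaled to unit diagonal.  Off-diagonal magnitudes that still reach 1
    are clipped (with a warning) so the result is usable as a Gaussian
    population correlation.
    """
    t = 0.5 * (target + target.T)
    np.fill_diagonal(t, 1.0)
    w, v = np.linalg.eigh(t)
    m = (v * np.maximum(w, eig_floor)) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    off = ~np.eye(m.shape[0], dtype=bool)
    if np.any(np.abs(m[off]) >= 1.0):
        warnings.warn(
            "off-diagonal correlations reached |1| after projection; clipping",
            UserWarning,
            stacklevel=2,
        )
        m[off] = np.clip(m[off], -0.999999, 0.999999)
    np.fill_diagonal(m, 1.0)
    return m


def simulate_timeseries(
    cohort: Cohort, n_timepoints: int, seed: int
) -> dict[tuple[str, str, int], np.ndarray]:
    """Stationary Gaussian nodal time series matching each session connectome.

    For every subject, session and run, draws ``n_timepoints`` samples from a
    multivariate normal whose population correlation matrix is the nearest
    positive-definite projection of that session's target connectome.  Runs
    within a session share the same target, so run-averaged sample FC
    converges to it faster than either single run.

    Returns a dict keyed by ``(subject, session, run)`` with (T, N) arrays.
    """
    rng = np.random.default_rng(seed)
    p = cohort.params
    out: dict[tuple[str, str, int], np.ndarray] = {}
    cset = cohort.connectomes
    for si, sub in enumerate(cset.subjects):
        for ti, ses in enumerate(cset.sessions):
            target = devectorize(cset.data[si, ti], p.n_nodes)
            corr = _nearest_pd_correlation(np.clip(target, -0.999, 0.999))
            chol = np.linalg.cholesky(corr)
            for run in range(p.n_runs_per_session):
                ts = rng.standard_normal((n_timepoints, p.n_nodes)) @ chol.T
                out[(sub, ses, run)] = ts
    return out


# ---------------------------------------------------------------------------
# on-disk layout: matrices as dense TSV, tables as TSV, truth as JSON sidecar


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write a cohort as delimited text files (one matrix per subject/session)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.parcellation.to_tsv(outdir / "parcellation.tsv")
    cohort.behaviours.to_csv(outdir / "behaviour.tsv", sep="\t", float_format="%.17g")
    cset = cohort.connectomes
    for si, sub in enumerate(cset.subjects):
        for ti, ses in enumerate(cset.sessions):
            m = devectorize(cset.data[si, ti], cset.n_nodes)
            np.savetxt(outdir / f"{sub}_{ses}.tsv", m, delimiter="\t", fmt="%.17g")
    truth = {
        "identity_edges": cohort.truth.identity_edges.tolist(),
        "behaviour_edges": cohort.truth.behaviour_edges.tolist(),
        "behaviour_weights": {
            str(int(e)): float(cohort.truth.behaviour_weights[e])
            for e in cohort.truth.behaviour_edges
        },
        "true_scores_noiseless": cohort.truth.true_scores_noiseless.tolist(),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def read_cohort(indir, params: CohortParams | None = None) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`.

    Also serves as the file-based ingest path for real data laid out the same
    way (the ground-truth sidecar is optional in that case).
    """
    indir = Path(indir)
    parc = Parcellation.from_tsv(indir / "parcellation.tsv")
    behaviours = pd.read_csv(indir / "behaviour.tsv", sep="\t", index_col="subject_id")
    matrices = sorted(indir.glob("sub*_ses*.tsv"))
    subjects = sorted({m.stem.split("_")[0] for m in matrices})
    sessions = sorted({m.stem.split("_")[1] for m in matrices})
    E = n_edges(parc.n_nodes)
    data = np.empty((len(subjects), len(sessions), E))
    for si, sub in enumerate(subjects):
        for ti, ses in enumerate(sessions):
            m = np.loadtxt(indir / f"{sub}_{ses}.tsv", delimiter="\t")
            data[si, ti] = vectorize_upper(m)
    cset = ConnectomeSet(subjects=subjects, sessions=sessions, n_nodes=parc.n_nodes, data=data)
    truth_path = indir / "ground_truth.json"
    if truth_path.exists():
        raw = json.loads(truth_path.read_text())
        weights = np.zeros(E)
        for k, v in raw["behaviour_weights"].items():
            weights[int(k)] = v
        truth = GroundTruth(
            identity_edges=np.asarray(raw["identity_edges"], dtype=int),
            behaviour_edges=np.asarray(raw["behaviour_edges"], dtype=int),
            behaviour_weights=weights,
            true_scores_noiseless=np.asarray(raw["true_scores_noiseless"], dtype=float),
        )
    else:
        truth = GroundTruth(
            identity_edges=np.array([], dtype=int),
            behaviour_edges=np.array([], dtype=int),
            behaviour_weights=np.zeros(E),
            true_scores_noiseless=np.zeros(len(subjects)),
        )
    if params is None:
        params = CohortParams(
            n_subjects=max(3, len(subjects)),
            n_nodes=parc.n_nodes,
            n_networks=len(parc.network_names),
            n_sessions=len(sessions),
        )
    return Cohort(
        params=params,
        parcellation=parc,
        connectomes=cset,
        behaviours=behaviours,
        truth=truth,
        session_targets=data,
    )
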