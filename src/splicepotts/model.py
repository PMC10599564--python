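"""Maximum-entropy (Potts) model of 9-nt donor sequences.

The model assigns every 9-mer S the Boltzmann probability

    P(S) = exp(-E(S)) / Z,      E(S) = -sum_i h_i(s_i) - sum_{i<j} J_ij(s_i, s_j)

with 36 field parameters h_i(s) and 576 pairwise couplings J_ij(s, t).  E is a
data-driven energy: low energy corresponds to frequent donor sequences.  The
state space (4^9 = 262144 sequences) is small enough that Z, gradients, model
marginals and exact sampling are all computed by full enumeration — no MCMC or
mean-field approximation anywhere.

Fitting minimizes the regularized negative log-likelihood

    NLL(h, J) + gamma * sum |J|,
    NLL = log Z - sum_i f_i . h_i - sum_{i<j} f_ij . J_ij

whose exact gradients are the marginal mismatches (P_i - f_i, P_ij - f_ij).
The L1 penalty on J (fields unpenalized) produces models in which most
couplings are exactly zero, mirroring the sparse coupling sets the analysis
revolves around.  The optimizer is a monotone accelerated proximal-gradient
scheme (MFISTA) with backtracking; the objective never increases across
accepted steps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.special import logsumexp

from .alphabet import (
    N_LETTER_PAIRS,
    N_LETTERS,
    N_PAIRS,
    N_POSITIONS,
    N_STATES,
    PAIRS,
    coupling_label,
    decode_sequences,
    encode_sequences,
    parse_coupling_label,
)
from .io import DonorEnsemble
from .marginals import MarginalSet

# The flat lexicographic state index factorizes into three blocks of three
# consecutive positions: idx = A * 64^2 + B * 64 + C with A = 16 s0 + 4 s1 + s2
# etc.  Full-grid work (adds/reductions over 262144 states) is organized
# around the (64, 64, 64) view so each evaluation touches the grid only a
# handful of times regardless of how many couplings are active.
_BLOCK = 64


def _block_offset(i: int) -> tuple[int, int]:
    return divmod(i, 3)


def _within_shape(oi: int, oj: int) -> tuple[int, ...]:
    s = [1, 1, 1]
    s[oi] = 4
    s[oj] = 4
    return tuple(s)


def _cross_shape(oi: int, oj: int) -> tuple[int, ...]:
    s = [1, 1, 1, 1, 1, 1]
    s[oi] = 4
    s[3 + oj] = 4
    return tuple(s)


@dataclass
class PottsModel:
    """Fields h (9x4), couplings J (36x16) and the regularization level gamma.

    Couplings shrunk away by the fitter are stored as exact zeros.  In the
    ``zero-sum-h`` gauge each field row sums to zero; gauge shifts move every
    energy by a constant and leave probabilities unchanged.
    """

    h: np.ndarray
    J: np.ndarray
    gamma: float = 0.0
    gauge_tag: str = ""
    fit_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.h.shape != (N_POSITIONS, N_LETTERS):
            raise ValueError(f"h must be 9x4, got {self.h.shape}")
        if self.J.shape != (N_PAIRS, N_LETTER_PAIRS):
            raise ValueError(f"J must be 36x16, got {self.J.shape}")
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("model parameters must be finite")

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        couplings = {}
        for p, (i, j) in enumerate(PAIRS):
            for ab in np.flatnonzero(self.J[p]):
                a, b = divmod(int(ab), 4)
                couplings[coupling_label(i, j, a, b)] = float(self.J[p, ab])
        doc = {
            "format": "splicepotts-potts-model",
            "letters": "ACGT",
            "positions": [-3, -2, -1, 1, 2, 3, 4, 5, 6],
            "h": self.h.tolist(),
            "J": couplings,
            "gamma": self.gamma,
            "gauge_tag": self.gauge_tag,
            "fit_metadata": self.fit_metadata,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PottsModel":
        doc = json.loads(text)
        J = np.zeros((N_PAIRS, N_LETTER_PAIRS))
        for label, value in doc["J"].items():
            i, j, a, b = parse_coupling_label(label)
            J[PAIRS.index((i, j)), 4 * a + b] = value
        return cls(
            np.array(doc["h"], dtype=float),
            J,
            gamma=doc.get("gamma", 0.0),
            gauge_tag=doc.get("gauge_tag", ""),
            fit_metadata=doc.get("fit_metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "PottsModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


class Coupling(NamedTuple):
    label: str
    i: int
    j: int
    a: int
    b: int
    value: float


def zero_sum_gauge(model: PottsModel) -> PottsModel:
    """Shift each field row to zero sum (probabilities unchanged)."""
    h = model.h - model.h.mean(axis=1, keepdims=True)
    return PottsModel(h, model.J.copy(), model.gamma, "zero-sum-h", dict(model.fit_metadata))


# -- enumeration machinery --------------------------------------------------

def _logit_grid(h: np.ndarray, J: np.ndarray) -> np.ndarray:
    """-E(S) for all 262144 states, flat, in lexicographic state order."""
    # per-block field sums (64,) and cross-block coupling planes (64, 64)
    blocks = [
        (
            h[3 * B][:, None, None]
            + h[3 * B + 1][None, :, None]
            + h[3 * B + 2][None, None, :]
        )
        for B in range(3)
    ]
    planes = {key: None for key in ((0, 1), (0, 2), (1, 2))}
    for p, (i, j) in enumerate(PAIRS):
        Jp = J[p]
        if not Jp.any():
            continue
        Bi, oi = _block_offset(i)
        Bj, oj = _block_offset(j)
        if Bi == Bj:
            blocks[Bi] += Jp.reshape(4, 4).reshape(_within_shape(oi, oj))
        else:
            if planes[(Bi, Bj)] is None:
                planes[(Bi, Bj)] = np.zeros((_BLOCK, _BLOCK))
            planes[(Bi, Bj)].reshape(4, 4, 4, 4, 4, 4)[:] += Jp.reshape(4, 4).reshape(
                _cross_shape(oi, oj)
            )
    A, B, C = (b.ravel() for b in blocks)
    ab = A[:, None] + B[None, :]
    if planes[(0, 1)] is not None:
        ab += planes[(0, 1)]
    g = ab[:, :, None] + C[None, None, :]
    if planes[(0, 2)] is not None:
        g += planes[(0, 2)][:, None, :]
    if planes[(1, 2)] is not None:
        g += planes[(1, 2)][None, :, :]
    return g.reshape(N_STATES)


def _marginals_from_grid(prob: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact one- and two-site marginals of a flat probability vector."""
    q = prob.reshape(_BLOCK, _BLOCK, _BLOCK)
    planes = {
        (0, 1): q.sum(axis=2),
        (0, 2): q.sum(axis=1),
        (1, 2): q.sum(axis=0),
    }
    block_marg = [
        planes[(0, 1)].sum(axis=1).reshape(4, 4, 4),
        planes[(0, 1)].sum(axis=0).reshape(4, 4, 4),
        planes[(0, 2)].sum(axis=0).reshape(4, 4, 4),
    ]
    P1 = np.empty((N_POSITIONS, N_LETTERS))
    for i in range(N_POSITIONS):
        Bi, oi = _block_offset(i)
        axes = tuple(k for k in range(3) if k != oi)
        P1[i] = block_marg[Bi].sum(axis=axes)
    P2 = np.empty((N_PAIRS, N_LETTER_PAIRS))
    for p, (i, j) in enumerate(PAIRS):
        Bi, oi = _block_offset(i)
        Bj, oj = _block_offset(j)
        if Bi == Bj:
            axes = tuple(k for k in range(3) if k not in (oi, oj))
            block = block_marg[Bi].sum(axis=axes)
            if oi > oj:  # keep letter at the smaller position first
                block = block.T
            P2[p] = block.ravel()
        else:
            plane = planes[(Bi, Bj)].reshape(4, 4, 4, 4, 4, 4)
            axes = tuple(k for k in range(6) if k not in (oi, 3 + oj))
            P2[p] = plane.sum(axis=axes).ravel()
    return P1, P2


def energy(model: PottsModel, seq: str) -> float:
    """Data-driven energy E(S) of a single 9-mer."""
    return float(energies(model, [seq])[0])


def energies(model: PottsModel, seqs) -> np.ndarray:
    """Vectorized energies of an iterable / ensemble of 9-mers."""
    if isinstance(seqs, DonorEnsemble):
        seqs = seqs.sequences
    codes = encode_sequences(seqs)
    if codes.shape[0] == 0:
        return np.zeros(0)
    e = -model.h[np.arange(N_POSITIONS), codes].sum(axis=1)
    for p, (i, j) in enumerate(PAIRS):
        Jp = model.J[p]
        if Jp.any():
            e -= Jp[codes[:, i] * 4 + codes[:, j]]
    return e


def partition_function(model: PottsModel) -> float:
    """log Z by numerically-stabilized summation over all 4^9 states."""
    return float(logsumexp(_logit_grid(model.h, model.J)))


def sequence_probability(model: PottsModel, seq: str) -> float:
    """Normalized Boltzmann probability of one sequence."""
    return float(math.exp(-energy(model, seq) - partition_function(model)))


def probability_grid(model: PottsModel) -> np.ndarray:
    """All 262144 state probabilities, flat in lexicographic state order."""
    g = _logit_grid(model.h, model.J)
    g -= logsumexp(g)
    return np.exp(g)


def model_marginals(model: PottsModel) -> MarginalSet:
    """Exact model one- and two-site marginals P_i, P_ij by enumeration."""
    P1, P2 = _marginals_from_grid(probability_grid(model))
    return MarginalSet(P1, P2, n_sequences=None, pseudocount=0.0)


def sample_sequences(
    model: PottsModel, n: int, seed: int, species_label: str = ""
) -> DonorEnsemble:
    """n i.i.d. exact draws from the model's categorical distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = probability_grid(model)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(N_STATES, size=n, p=p)
    digits = np.empty((n, N_POSITIONS), dtype=np.uint8)
    rem = idx
    for k in range(N_POSITIONS - 1, -1, -1):
        digits[:, k] = rem % 4
        rem = rem // 4
    return DonorEnsemble(decode_sequences(digits), species_label=species_label)


def active_couplings(model: PottsModel) -> list[Coupling]:
    """Exactly-nonzero couplings, sorted by |J| descending."""
    out = []
    for p, (i, j) in enumerate(PAIRS):
        for ab in np.flatnonzero(model.J[p]):
            a, b = divmod(int(ab), 4)
            out.append(
                Coupling(coupling_label(i, j, a, b), i, j, a, b, float(model.J[p, ab]))
            )
    out.sort(key=lambda c: (-abs(c.value), c.i, c.j, c.a, c.b))
    return out


# -- fitting ----------------------------------------------------------------

def _smooth_eval(h, J, f1, f2, want_marginals):
    """NLL value (and optionally exact marginals) at (h, J)."""
    g = _logit_grid(h, J)
    logz = logsumexp(g)
    value = logz - float((f1 * h).sum()) - float((f2 * J).sum())
    if not want_marginals:
        return value, None, None
    prob = np.exp(g - logz)
    P1, P2 = _marginals_from_grid(prob)
    return value, P1, P2


def _soft_threshold(x: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def fit_maxent(
    target: MarginalSet,
    gamma: float,
    *,
    max_iter: int = 2000,
    tol_obj: float = 1e-9,
    tol_kkt: float = 1e-5,
    tol_marginal: float = 1e-5,
    check_every: int = 10,
    init: PottsModel | None = None,
    trace: bool = False,
) -> PottsModel:
    """Fit fields and L1-sparse couplings to target marginals.

    Minimizes ``NLL(h, J) + gamma * sum|J|`` by monotone accelerated
    proximal-gradient descent with backtracking line search; gradients and the
    partition function are exact (full enumeration).  Convergence requires the
    relative objective change, the KKT violation on J, and the one-site
    marginal residual max|P_i - f_i| to fall below their tolerances.  The
    returned model is in the zero-sum-h gauge; non-convergence is reported in
    ``fit_metadata['converged']`` rather than raised.

    Target marginals must be strictly positive (fit to pseudocounted
    marginals; see :func:`splicepotts.marginals.estimate_marginals`).
    """
    f1 = np.asarray(target.f1, dtype=float)
    f2 = np.asarray(target.f2, dtype=float)
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if (f1 <= 0).any() or (f2 <= 0).any():
        raise ValueError(
            "target marginals contain zero or negative entries; estimate them "
            "with a positive pseudocount before fitting"
        )

    if init is not None:
        h = init.h.copy()
        J = init.J.copy()
    else:
        h = np.log(f1)
        h -= h.mean(axis=1, keepdims=True)
        J = np.zeros((N_PAIRS, N_LETTER_PAIRS))

    def full_objective(val_smooth, Jx):
        return val_smooth + gamma * np.abs(Jx).sum()

    x_h, x_J = h, J
    y_h, y_J = h, J
    t = 1.0
    L = 1.0
    gx, P1x, P2x = _smooth_eval(x_h, x_J, f1, f2, True)
    Fx = full_objective(gx, x_J)
    n_iter = 0
    converged = False
    kkt = np.inf
    marg = np.inf

    def diagnostics(P1, P2, Jx):
        grad_J = P2 - f2
        viol_active = np.abs(grad_J + gamma * np.sign(Jx))[Jx != 0]
        viol_zero = np.maximum(np.abs(grad_J[Jx == 0]) - gamma, 0.0)
        kkt = max(
            viol_active.max() if viol_active.size else 0.0,
            viol_zero.max() if viol_zero.size else 0.0,
        )
        marg = float(np.abs(P1 - f1).max())
        return float(kkt), marg

    kkt, marg = diagnostics(P1x, P2x, x_J)
    if kkt <= tol_kkt and marg <= tol_marginal:
        converged = True
    objective_trace = [float(Fx)]

    for n_iter in range(1, max_iter + 1):
        if converged:
            n_iter -= 1
            break
        gy, P1y, P2y = _smooth_eval(y_h, y_J, f1, f2, True)
        grad_h = P1y - f1
        grad_J = P2y - f2
        # backtracking proximal step from y
        while True:
            step = 1.0 / L
            z_h = y_h - step * grad_h
            z_J = _soft_threshold(y_J - step * grad_J, gamma * step)
            gz, _, _ = _smooth_eval(z_h, z_J, f1, f2, False)
            dh = z_h - y_h
            dJ = z_J - y_J
            quad = (
                gy
                + float((grad_h * dh).sum())
                + float((grad_J * dJ).sum())
                + 0.5 * L * (float((dh * dh).sum()) + float((dJ * dJ).sum()))
            )
            if gz <= quad + 1e-12 * max(1.0, abs(quad)):
                break
            L *= 2.0
            if L > 1e12:
                break
        Fz = full_objective(gz, z_J)
        # monotone safeguard with restart: never accept an objective increase
        if Fz <= Fx:
            t_next = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t * t))
            y_h = z_h + ((t - 1.0) / t_next) * (z_h - x_h)
            y_J = z_J + ((t - 1.0) / t_next) * (z_J - x_J)
            rel_change = (Fx - Fz) / max(1.0, abs(Fz))
            x_h, x_J, Fx = z_h, z_J, Fz
            t = t_next
        else:
            # momentum restart: next step is a plain proximal step from x
            y_h, y_J = x_h, x_J
            t = 1.0
            rel_change = 0.0
        L = max(L * 0.9, 1e-3)
        if trace:
            objective_trace.append(float(Fx))

        if n_iter % check_every == 0 or n_iter == max_iter:
            gx, P1x, P2x = _smooth_eval(x_h, x_J, f1, f2, True)
            kkt, marg = diagnostics(P1x, P2x, x_J)
            if kkt <= tol_kkt and marg <= tol_marginal and rel_change <= tol_obj:
                converged = True

    metadata = {
        "iterations": n_iter,
        "final_objective": float(Fx),
        "max_marginal_residual": marg,
        "kkt_violation": kkt,
        "converged": bool(converged),
    }
    if trace:
        metadata["objective_trace"] = objective_trace
    model = PottsModel(x_h, x_J, gamma=gamma, gauge_tag="", fit_metadata=metadata)
    return zero_sum_gauge(model)
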