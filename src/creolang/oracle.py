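"""Exact Markov-chain treatment of tiny populations.

For a handful of Mulatto/Bozal agents the dynamics is a finite Markov chain
over group-wise multisets of repertoires (agents of the same group and
repertoire are exchangeable).  The chain is built by exact enumeration of
every (pair draw, role assignment, epsilon gate, utterance, delta draw,
gamma draw) outcome under the *same* rule variants as the simulation
engine, and serves as the independent reference for validating it.

One counted step of the chain corresponds to one counted interaction of the
engine: European–European draws are conditioned away (they are discarded
without advancing time), while epsilon-rejected European–Bozal draws are
self-transitions when ``epsilon_null_advances_time`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from math import comb

import numpy as np

from .errors import InternalConsistencyError, StateSpaceTooLargeError
from .model import A_MASK, C_MASK, E_MASK, ModelParams, _popcount

# the 7 possible repertoires as bit masks: {E},{A},{AE},{C},{EC},{AC},{AEC}
REP_MASKS = (1, 2, 3, 4, 5, 6, 7)

# ChainState: (tuple of sorted M masks, tuple of sorted B masks)
ChainState = tuple[tuple[int, ...], tuple[int, ...]]

_STATE_GUARD = 100_000


@dataclass
class ChainModel:
    """Exact chain: state list, index map, dense row-stochastic matrix."""

    n_eu: int
    n_m: int
    n_b: int
    params: ModelParams
    states: list[ChainState]
    index: dict[ChainState, int]
    P: np.ndarray
    all_e_index: int

    @property
    def n_states(self) -> int:
        return len(self.states)


def enumerate_states(n_m: int, n_b: int) -> list[ChainState]:
    """All group-wise repertoire multisets for n_m Mulattos and n_b Bozals."""
    if n_m + n_b < 1:
        raise ValueError("need at least one Mulatto or Bozal")
    n_states = comb(n_m + 6, 6) * comb(n_b + 6, 6)
    if n_states > _STATE_GUARD:
        raise StateSpaceTooLargeError(
            f"{n_states} states exceeds the guard of {_STATE_GUARD}"
        )
    m_multisets = list(combinations_with_replacement(REP_MASKS, n_m))
    b_multisets = list(combinations_with_replacement(REP_MASKS, n_b))
    return [(m, b) for m in m_multisets for b in b_multisets]


def initial_state(n_m: int, n_b: int) -> ChainState:
    """Mulattos all {E}, Bozals all {A}."""
    return ((E_MASK,) * n_m, (A_MASK,) * n_b)


def _hearer_outcomes(
    h_mask: int, utt: int, speaker_is_eu: bool, s_mask: int, params: ModelParams
) -> list[tuple[float, int, int]]:
    """Exact distribution of (probability, new_speaker_mask, new_hearer_mask)."""
    out: list[tuple[float, int, int]] = []  # before creolization: (p, s', h', changed)
    pre: list[tuple[float, int, int, bool]] = []
    if h_mask & utt == 0:
        pre.append((1.0, s_mask, h_mask | utt, True))
    else:
        p_succ = 1.0 if utt != A_MASK else params.delta
        new_s = utt if not speaker_is_eu else s_mask
        if p_succ > 0.0:
            pre.append((p_succ, new_s, utt, h_mask != utt))
        if p_succ < 1.0:
            pre.append((1.0 - p_succ, s_mask, h_mask, False))
    for p, s_new, h_new, changed in pre:
        check = (h_new & 3) == 3 and (
            not params.creolize_only_on_change or changed
        )
        if check and params.gamma > 0.0:
            out.append((p * params.gamma, s_new, C_MASK))
            if params.gamma < 1.0:
                out.append((p * (1.0 - params.gamma), s_new, h_new))
        else:
            out.append((p, s_new, h_new))
    return out


def build_transition_matrix(
    n_eu: int, n_m: int, n_b: int, params: ModelParams
) -> ChainModel:
    """Exact one-step transition matrix over repertoire multisets."""
    states = enumerate_states(n_m, n_b)
    index = {s: k for k, s in enumerate(states)}
    n = n_eu + n_m + n_b
    pairs_total = comb(n, 2) - comb(n_eu, 2)  # Eu–Eu draws conditioned away
    P = np.zeros((len(states), len(states)))

    for row, (m_reps, b_reps) in enumerate(states):
        # category list: (group, mask, count); group 0 = M, 1 = B
        cats: list[tuple[int, int, int]] = []
        for mask in REP_MASKS:
            cm = m_reps.count(mask)
            if cm:
                cats.append((0, mask, cm))
            cb = b_reps.count(mask)
            if cb:
                cats.append((1, mask, cb))

        def add(p: float, group_s, mask_s, new_s, group_h, mask_h, new_h) -> None:
            """Move one agent of (group_s, mask_s) to new_s and likewise for
            the hearer, then accumulate probability into the target row."""
            mm, bb = list(m_reps), list(b_reps)
            for grp, old, new in ((group_s, mask_s, new_s), (group_h, mask_h, new_h)):
                if grp is None or old == new:
                    continue
                seq = mm if grp == 0 else bb
                seq.remove(old)
                seq.append(new)
            target = (tuple(sorted(mm)), tuple(sorted(bb)))
            P[row, index[target]] += p

        # --- pairs with one European (speaker, utters E) ---
        for g, mask, cnt in cats:
            p_pair = n_eu * cnt / pairs_total
            if p_pair == 0.0:
                continue
            if g == 1 and params.epsilon < 1.0:
                # epsilon-rejected Eu–B draw: null self-transition
                P[row, row] += p_pair * (1.0 - params.epsilon)
            p_go = p_pair * (params.epsilon if g == 1 else 1.0)
            if p_go == 0.0:
                continue
            for p, _, h_new in _hearer_outcomes(mask, E_MASK, True, E_MASK, params):
                add(p_go * p, None, 0, 0, g, mask, h_new)

        # --- pairs of two non-Europeans, roles by fair coin ---
        for a_idx, (ga, ma, ca) in enumerate(cats):
            for gb, mb, cb in cats[a_idx:]:
                same = (ga, ma) == (gb, mb)
                n_pairs = ca * (ca - 1) // 2 if same else ca * cb
                p_pair = n_pairs / pairs_total
                if p_pair == 0.0:
                    continue
                ordered = [((ga, ma), (gb, mb))] if same else [
                    ((ga, ma), (gb, mb)),
                    ((gb, mb), (ga, ma)),
                ]
                p_role = p_pair if same else p_pair * 0.5
                for (gs, ms), (gh, mh) in ordered:
                    size = int(_popcount(np.array([ms]))[0])
                    for utt in (E_MASK, A_MASK, C_MASK):
                        if ms & utt == 0:
                            continue
                        p_utt = p_role / size
                        for p, s_new, h_new in _hearer_outcomes(
                            mh, utt, False, ms, params
                        ):
                            add(p_utt * p, gs, ms, s_new, gh, mh, h_new)

        row_sum = P[row].sum()
        if abs(row_sum - 1.0) > 1e-12:
            raise InternalConsistencyError(
                f"row {row} sums to {row_sum!r}, mass unaccounted"
            )

    all_e = ((E_MASK,) * n_m, (E_MASK,) * n_b)
    model = ChainModel(
        n_eu=n_eu,
        n_m=n_m,
        n_b=n_b,
        params=params,
        states=states,
        index=index,
        P=P,
        all_e_index=index[all_e],
    )
    ae = model.all_e_index
    if abs(P[ae, ae] - 1.0) > 1e-12:
        raise InternalConsistencyError("all-E state is not absorbing")
    P[ae, :] = 0.0
    P[ae, ae] = 1.0  # pin the absorbing row exactly
    return model


def distribution_after(
    model: ChainModel, start: ChainState, horizon: int
) -> np.ndarray:
    """State distribution after `horizon` counted steps from `start`."""
    v = np.zeros(model.n_states)
    v[model.index[start]] = 1.0
    # repeated squaring of P: horizon can be thousands of steps
    P = model.P
    h = horizon
    while h > 0:
        if h & 1:
            v = v @ P
        P = P @ P
        h >>= 1
    return v


def absorption_probability_all_E(
    model: ChainModel, start: ChainState, horizon: int | float = np.inf
) -> float:
    """Probability of sitting in the all-E absorbing state.

    Finite horizon: mass on all-E after exactly `horizon` steps.  Infinite
    horizon: limit from the fundamental-matrix decomposition over the
    transient states.
    """
    if np.isfinite(horizon):
        return float(distribution_after(model, start, int(horizon))[model.all_e_index])
    P = model.P
    absorbing = np.isclose(np.diag(P), 1.0)
    if start == model.states[model.all_e_index]:
        return 1.0
    transient = ~absorbing
    t_idx = np.where(transient)[0]
    pos = {s: k for k, s in enumerate(t_idx)}
    start_i = model.index[start]
    if absorbing[start_i]:
        return 0.0
    Q = P[np.ix_(t_idx, t_idx)]
    r = P[t_idx, model.all_e_index]
    try:
        h = np.linalg.solve(np.eye(len(t_idx)) - Q, r)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise InternalConsistencyError(
            f"fundamental-matrix solve failed: {exc}"
        ) from exc
    return float(h[pos[start_i]])


def expected_fractions(
    model: ChainModel, start: ChainState, horizon: int
) -> tuple[float, float, float]:
    """Expected (f_E, f_A, f_C) under split weighting after `horizon` steps."""
    v = distribution_after(model, start, horizon)
    f = np.zeros(3)
    for p, (m_reps, b_reps) in zip(v, model.states):
        if p == 0.0:
            continue
        w = np.zeros(3)
        for mask in m_reps + b_reps:
            size = bin(mask).count("1")
            for k, lm in enumerate((E_MASK, A_MASK, C_MASK)):
                if mask & lm:
                    w[k] += 1.0 / size
        f += p * w / len(m_reps + b_reps)
    return float(f[0]), float(f[1]), float(f[2])
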