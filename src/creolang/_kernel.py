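"""Numba inner loop for the Naming-Game dynamics.

Applies exactly the rules of :mod:`creolang.model` (same pair-draw topology,
epsilon gate, learning/collapse, delta intelligibility, gamma creolization)
over bit-mask repertoires.  Paper-scale runs need tens of millions of
elementary interactions, so the loop is jitted; its agreement with the
definitional layer is checked against the exact Markov chain in the tests.
"""

import numpy as np
from numba import njit

# per-mask lookup tables: weight contributed to each language under split
# weighting (1/|repertoire| per language held), index = repertoire bit mask
_W_E = np.array([0.0, 1.0, 0.0, 0.5, 0.0, 0.5, 0.0, 1 / 3])
_W_A = np.array([0.0, 0.0, 1.0, 0.5, 0.0, 0.0, 0.5, 1 / 3])
_W_C = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 0.5, 0.5, 1 / 3])
_POP = np.array([0, 1, 1, 2, 1, 2, 2, 3], dtype=np.int64)


@njit(cache=True)
def simulate(
    masks,            # uint8[n_m + n_b], mutated in place
    n_eu,
    n_m,
    gamma,
    delta,
    epsilon,
    max_steps,
    tail_start,
    creolize_always,
    null_advances,
    monolingual_weighting,
    seed,
):
    """Iterate the dynamics; returns (acc_E, acc_A, acc_C, absorbed, steps).

    acc_* are language weights summed over the tail window (steps with
    index >= tail_start); if the all-E state is reached early the
    remaining window is accumulated as all-E.
    """
    np.random.seed(seed)
    n_mb = masks.shape[0]
    n = n_eu + n_mb

    # running split-weight totals and monolingual counts per language
    w_e = 0.0
    w_a = 0.0
    w_c = 0.0
    mono = np.zeros(3, dtype=np.int64)
    non_e = 0  # agents whose repertoire is not exactly {E}
    for k in range(n_mb):
        m = masks[k]
        w_e += _W_E[m]
        w_a += _W_A[m]
        w_c += _W_C[m]
        if m == 1:
            mono[0] += 1
        elif m == 2:
            mono[1] += 1
        elif m == 4:
            mono[2] += 1
        if m != 1:
            non_e += 1

    acc_e = 0.0
    acc_a = 0.0
    acc_c = 0.0
    absorbed = False
    t = 0
    while t < max_steps:
        # ---- draw an unordered pair; Eu–Eu pairs are no-ops, redrawn ----
        while True:
            i = np.random.randint(0, n)
            j = np.random.randint(0, n)
            if i == j:
                continue
            if i < n_eu and j < n_eu:
                continue
            break

        null_step = False
        s = -1  # speaker index into masks; -1 = European speaker
        if i < n_eu or j < n_eu:
            h = (j if i < n_eu else i) - n_eu
            if h >= n_m and np.random.random() >= epsilon:
                # epsilon-rejected European–Bozal draw
                if not null_advances:
                    continue
                null_step = True
        else:
            if np.random.random() < 0.5:
                s = i - n_eu
                h = j - n_eu
            else:
                s = j - n_eu
                h = i - n_eu

        if not null_step:
            # ---- utterance: uniform over the speaker's repertoire ----
            if s < 0:
                utt = 1  # Europeans utter E
            else:
                sm = masks[s]
                size = _POP[sm]
                if size == 1:
                    utt = sm
                else:
                    pick = np.random.randint(0, size)
                    utt = 0
                    for b in range(3):
                        bit = 1 << b
                        if sm & bit:
                            if pick == 0:
                                utt = bit
                                break
                            pick -= 1

            # ---- learning / collapse rules ----
            old_h = masks[h]
            new_h = old_h
            if old_h & utt == 0:
                new_h = old_h | utt  # (a) learn the unknown language
            else:
                # (b) success always for E/C, with probability delta for A
                if utt != 2 or np.random.random() < delta:
                    new_h = utt
                    if s >= 0 and masks[s] != utt:
                        old_s = masks[s]
                        masks[s] = utt
                        w_e += _W_E[utt] - _W_E[old_s]
                        w_a += _W_A[utt] - _W_A[old_s]
                        w_c += _W_C[utt] - _W_C[old_s]
                        if _POP[old_s] == 1:
                            mono[0 if old_s == 1 else (1 if old_s == 2 else 2)] -= 1
                        mono[0 if utt == 1 else (1 if utt == 2 else 2)] += 1
                        if old_s == 1:
                            non_e += 1
                        if utt == 1:
                            non_e -= 1

            # ---- creolization check on the hearer ----
            if (new_h & 3) == 3 and (creolize_always or new_h != old_h):
                if np.random.random() < gamma:
                    new_h = 4

            if new_h != old_h:
                masks[h] = new_h
                w_e += _W_E[new_h] - _W_E[old_h]
                w_a += _W_A[new_h] - _W_A[old_h]
                w_c += _W_C[new_h] - _W_C[old_h]
                if _POP[old_h] == 1:
                    mono[0 if old_h == 1 else (1 if old_h == 2 else 2)] -= 1
                if _POP[new_h] == 1:
                    mono[0 if new_h == 1 else (1 if new_h == 2 else 2)] += 1
                if old_h == 1:
                    non_e += 1
                if new_h == 1:
                    non_e -= 1

        # ---- tail-window accumulation ----
        if t >= tail_start:
            if monolingual_weighting and mono[0] + mono[1] + mono[2] > 0:
                tot = mono[0] + mono[1] + mono[2]
                acc_e += n_mb * mono[0] / tot
                acc_a += n_mb * mono[1] / tot
                acc_c += n_mb * mono[2] / tot
            else:
                acc_e += w_e
                acc_a += w_a
                acc_c += w_c

        t += 1
        if non_e == 0:
            absorbed = True
            break

    if absorbed and t < max_steps:
        # frozen all-E state fills the rest of the tail window
        remaining = max_steps - max(t, tail_start)
        if remaining > 0:
            acc_e += n_mb * remaining

    return acc_e, acc_a, acc_c, absorbed, t
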