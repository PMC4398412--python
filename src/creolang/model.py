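"""Agent-level Naming-Game dynamics for contact-language emergence.

The model follows a three-group contact ecology: Europeans (``EU``) are an
immutable source of the lexifier ``E``; Free Colored / Mulattos (``M``) start
with ``E``; Bozal slaves (``B``) start with the coarse-grained African
substrate ``A``.  Pairwise speaker/hearer games exchange languages, a success
collapses both repertoires to the uttered language, and a hearer left holding
both ``A`` and ``E`` creolizes to the hybrid ``C`` with probability ``gamma``.

Two more probabilities shape the ecology: ``delta``, the chance that two
``A``-speakers understand each other (African multilingualism modelled in an
average way), and ``epsilon``, the chance that a drawn European–Bozal pair
actually interacts (segregation).

This module is the definitional, step-by-step implementation.  :func:`run`
delegates the inner loop to a numba kernel (:mod:`creolang._kernel`) that
applies exactly the same rules; the exact-chain module provides the
independent check that the two agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np

from .errors import (
    InvalidPopulationError,
    InvariantViolationError,
    TopologyViolationError,
)
from . import _kernel

# Languages are encoded as bit masks so a repertoire is one uint8 in {1..7}.
E, A, C = "E", "A", "C"
LANGUAGES: tuple[str, str, str] = (E, A, C)
MASK: dict[str, int] = {E: 1, A: 2, C: 4}
E_MASK, A_MASK, C_MASK = 1, 2, 4

# group labels
EU, M, B = "EU", "M", "B"

NULL_STEP = "null_step"


def mask_of(rep: Iterable[str]) -> int:
    """Encode a repertoire (iterable of language labels) as a bit mask."""
    m = 0
    for lang in rep:
        m |= MASK[lang]
    if m == 0:
        raise InvariantViolationError("repertoire must be non-empty")
    return m


def rep_of(mask: int) -> frozenset[str]:
    """Decode a bit mask into a frozenset of language labels."""
    if not 1 <= mask <= 7:
        raise InvariantViolationError(f"invalid repertoire mask {mask}")
    return frozenset(l for l in LANGUAGES if mask & MASK[l])


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one simulation run.

    Parameters
    ----------
    gamma
        Creolization probability: a hearer holding both A and E retains
        only C with this probability after an interaction.
    delta
        Probability that an uttered A is intelligible to a hearer who
        already has A in her repertoire.
    epsilon
        Probability that a drawn European–Bozal pair actually interacts
        (segregation parameter).
    dominance_threshold
        Tail-averaged fraction above which a language is said to dominate.
    max_interactions_per_agent
        Run horizon: total interactions = this value times (n_m + n_b).
    tail_window_fraction
        Final fraction of the horizon over which fractions are
        time-averaged to define the asymptotic state.
    creolize_only_on_change
        If True, the creolization check fires only when the hearer's
        repertoire changed in the interaction (stricter variant); the
        default checks after every interaction the hearer takes part in.
    epsilon_null_advances_time
        If True (default), an epsilon-rejected European–Bozal draw counts
        as an elapsed interaction; if False it is redrawn without
        advancing time (affects time scale only).
    weighting
        ``"split"`` gives each agent weight 1/|repertoire| per language
        held; ``"monolingual"`` counts only single-language agents.
    seed
        Base seed; replicate r of a multi-run experiment uses seed + r.
    """

    gamma: float
    delta: float
    epsilon: float
    dominance_threshold: float = 0.8
    max_interactions_per_agent: int = 2000
    tail_window_fraction: float = 0.1
    creolize_only_on_change: bool = False
    epsilon_null_advances_time: bool = True
    weighting: Literal["split", "monolingual"] = "split"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gamma", "delta", "epsilon"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if not 0.0 < self.dominance_threshold <= 1.0:
            raise ValueError("dominance_threshold must be in (0, 1]")
        if self.max_interactions_per_agent < 1:
            raise ValueError("max_interactions_per_agent must be >= 1")
        if not 0.0 < self.tail_window_fraction < 1.0:
            raise ValueError("tail_window_fraction must be in (0, 1)")
        if self.weighting not in ("split", "monolingual"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass
class PopulationState:
    """Mutable population state.

    Agents are indexed ``0 .. N-1``: Europeans first, then Mulattos, then
    Bozals.  Only Mulatto and Bozal repertoires are stored (``masks``,
    length ``n_m + n_b``); Europeans are implicitly fixed at {E}.
    """

    n_eu: int
    n_m: int
    n_b: int
    masks: np.ndarray  # uint8, length n_m + n_b
    interactions_elapsed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_eu + self.n_m + self.n_b

    def group_of(self, agent: int) -> str:
        if not 0 <= agent < self.n_total:
            raise IndexError(f"agent index {agent} out of range")
        if agent < self.n_eu:
            return EU
        if agent < self.n_eu + self.n_m:
            return M
        return B

    def repertoire(self, agent: int) -> frozenset[str]:
        """Repertoire of any agent; Europeans always return {E}."""
        if self.group_of(agent) == EU:
            return frozenset((E,))
        return rep_of(int(self.masks[agent - self.n_eu]))

    def copy(self) -> "PopulationState":
        return replace(self, masks=self.masks.copy())


@dataclass(frozen=True)
class InteractionOutcome:
    """Record of one elementary interaction (instrumentation)."""

    speaker_group: str
    hearer_group: str
    uttered: str | None
    result: str  # "learned" | "success" | "failed_A" | "null_step"
    creolized: bool


@dataclass(frozen=True)
class FractionSummary:
    """Language fractions over the Mulatto + Bozal population."""

    f_E: float
    f_A: float
    f_C: float

    def dominant(self, threshold: float = 0.8) -> str | None:
        """Label of the language whose fraction exceeds the threshold."""
        for lang, f in zip(LANGUAGES, (self.f_E, self.f_A, self.f_C)):
            if f > threshold:
                return lang
        return None


def init_population(
    n_eu: int, n_m: int, n_b: int, params: ModelParams | None = None
) -> PopulationState:
    """Initial state: Europeans and Mulattos speak E, Bozals speak A."""
    if min(n_eu, n_m, n_b) < 0:
        raise InvalidPopulationError("subpopulation counts must be non-negative")
    if n_m + n_b < 1:
        raise InvalidPopulationError(
            "no Mulattos or Bozals: no hearers exist, dynamics undefined"
        )
    masks = np.empty(n_m + n_b, dtype=np.uint8)
    masks[:n_m] = E_MASK
    masks[n_m:] = A_MASK
    return PopulationState(n_eu=n_eu, n_m=n_m, n_b=n_b, masks=masks)


def draw_pair(
    state: PopulationState, params: ModelParams, rng: np.random.Generator
) -> tuple[int, int] | None:
    """Draw a (speaker, hearer) pair of agent indices, or None for a null step.

    An unordered pair of distinct agents is drawn uniformly; a pair of two
    Europeans is discarded and redrawn (it is a no-op by construction and
    does not advance time).  A European in a mixed pair is always the
    Speaker.  A drawn European–Bozal pair is retained with probability
    epsilon; otherwise a null step (None) is returned.  Two non-European
    agents get their roles by fair coin.
    """
    n = state.n_total
    if n < 2:
        raise InvalidPopulationError("need at least two agents to draw a pair")
    while True:
        i = int(rng.integers(n))
        j = int(rng.integers(n))
        if i == j:
            continue
        if i < state.n_eu and j < state.n_eu:
            continue  # Eu–Eu: no-op, redraw without advancing time
        break
    if i < state.n_eu or j < state.n_eu:
        speaker, hearer = (i, j) if i < state.n_eu else (j, i)
        if state.group_of(hearer) == B and rng.random() >= params.epsilon:
            return None
        return speaker, hearer
    if rng.random() < 0.5:
        return i, j
    return j, i


def utter(speaker_rep: frozenset[str], rng: np.random.Generator) -> str:
    """Speaker picks a language uniformly at random from her repertoire."""
    if not speaker_rep:
        raise InvariantViolationError("speaker repertoire is empty")
    members = sorted(speaker_rep)  # sorted for reproducibility
    return members[int(rng.integers(len(members)))]


def creolization_check(
    rep: frozenset[str], gamma: float, rng: np.random.Generator
) -> frozenset[str]:
    """Hearer holding both A and E retains only C with probability gamma."""
    if not rep:
        raise InvariantViolationError("repertoire is empty")
    if {A, E} <= rep and rng.random() < gamma:
        return frozenset((C,))
    return rep


def apply_interaction(
    state: PopulationState,
    speaker: int,
    hearer: int,
    uttered: str,
    params: ModelParams,
    rng: np.random.Generator,
) -> InteractionOutcome:
    """Apply the learning/collapse rules and the creolization check.

    (a) a hearer lacking the uttered language learns it (adds it to her
    repertoire); (b) a hearer who has it communicates successfully — always
    for E or C, with probability delta for A — and on success both agents
    retain only the uttered language.  Afterwards the creolization check is
    applied to the hearer.  Mutates ``state`` in place.
    """
    h_group = state.group_of(hearer)
    if h_group == EU:
        raise TopologyViolationError("Europeans can only act as Speaker")
    s_group = state.group_of(speaker)
    if uttered not in state.repertoire(speaker):
        raise InvariantViolationError(
            f"speaker cannot utter {uttered}: not in repertoire"
        )

    h = hearer - state.n_eu
    old_mask = int(state.masks[h])
    utt_mask = MASK[uttered]

    if old_mask & utt_mask == 0:
        state.masks[h] = old_mask | utt_mask
        result = "learned"
    else:
        success = uttered != A or rng.random() < params.delta
        if success:
            state.masks[h] = utt_mask
            if s_group != EU:
                state.masks[speaker - state.n_eu] = utt_mask
            result = "success"
        else:
            result = "failed_A"

    hearer_changed = int(state.masks[h]) != old_mask
    creolized = False
    if not params.creolize_only_on_change or hearer_changed:
        new_rep = creolization_check(rep_of(int(state.masks[h])), params.gamma, rng)
        if new_rep == frozenset((C,)) and int(state.masks[h]) != C_MASK:
            state.masks[h] = C_MASK
            creolized = True
    return InteractionOutcome(
        speaker_group=s_group,
        hearer_group=h_group,
        uttered=uttered,
        result=result,
        creolized=creolized,
    )


def step(
    state: PopulationState, params: ModelParams, rng: np.random.Generator
) -> InteractionOutcome:
    """One elementary step: draw a pair, utter, apply the rules.

    A null step (epsilon-rejected European–Bozal draw) advances the
    interaction counter when ``params.epsilon_null_advances_time`` is set.
    """
    while True:
        pair = draw_pair(state, params, rng)
        if pair is None:
            if params.epsilon_null_advances_time:
                state.interactions_elapsed += 1
                return InteractionOutcome(EU, B, None, NULL_STEP, False)
            continue
        speaker, hearer = pair
        uttered = utter(state.repertoire(speaker), rng)
        outcome = apply_interaction(state, speaker, hearer, uttered, params, rng)
        state.interactions_elapsed += 1
        return outcome


def measure_fractions(
    state: PopulationState, weighting: str = "split"
) -> FractionSummary:
    """Instantaneous language fractions among Mulattos + Bozals.

    With ``"split"`` weighting each agent contributes 1/|repertoire| to
    every language she holds; ``"monolingual"`` counts only agents with a
    single language (renormalized; all-bilingual populations fall back to
    split weighting to stay well defined).
    """
    if state.n_m + state.n_b < 1:
        raise InvalidPopulationError("no Mulattos or Bozals to measure")
    masks = state.masks
    if weighting == "monolingual":
        mono = np.isin(masks, (E_MASK, A_MASK, C_MASK))
        if mono.any():
            masks = masks[mono]
        # else: no monolingual agent; fall through to split weighting
    counts = np.zeros(3)
    sizes = _popcount(masks)
    for k, lm in enumerate((E_MASK, A_MASK, C_MASK)):
        counts[k] = np.sum((masks & lm != 0) / sizes)
    counts /= counts.sum()
    return FractionSummary(f_E=counts[0], f_A=counts[1], f_C=counts[2])


def _popcount(masks: np.ndarray) -> np.ndarray:
    m = masks.astype(np.uint8)
    return (m & 1) + ((m >> 1) & 1) + ((m >> 2) & 1)


def run(
    state: PopulationState,
    params: ModelParams,
    seed: int | None = None,
) -> tuple[PopulationState, FractionSummary, bool]:
    """Run the dynamics to the quasi-stationary regime.

    Iterates ``max_interactions_per_agent * (n_m + n_b)`` interactions,
    exiting early if the all-E absorbing state is reached (A and C extinct).
    The returned :class:`FractionSummary` is the time average over the final
    ``tail_window_fraction`` of the nominal horizon; if the run absorbs
    earlier, the remaining window is accounted as the frozen all-E state.

    Returns ``(final_state, tail_summary, absorbed_all_E)``.
    """
    if state.n_m + state.n_b < 1:
        raise InvalidPopulationError("no Mulattos or Bozals: nothing to run")
    if state.n_total < 2:
        raise InvalidPopulationError("need at least two agents to run")
    if (
        params.epsilon == 0.0
        and not params.epsilon_null_advances_time
        and state.n_m == 0
        and state.n_b == 1
    ):
        raise InvalidPopulationError(
            "epsilon=0 with a lone Bozal and non-counting null steps can "
            "never produce an interaction"
        )
    if seed is None:
        seed = params.seed
    seed = int(seed) % (2**31)
    max_steps = params.max_interactions_per_agent * (state.n_m + state.n_b)
    tail_start = max_steps - max(1, int(round(params.tail_window_fraction * max_steps)))
    acc_e, acc_a, acc_c, absorbed, steps = _kernel.simulate(
        state.masks,
        state.n_eu,
        state.n_m,
        params.gamma,
        params.delta,
        params.epsilon,
        max_steps,
        tail_start,
        not params.creolize_only_on_change,
        params.epsilon_null_advances_time,
        params.weighting == "monolingual",
        seed,
    )
    state.interactions_elapsed += int(steps)
    total = acc_e + acc_a + acc_c
    # accumulators are maintained incrementally; clamp float drift at zero
    f_e, f_a, f_c = (max(0.0, v / total) for v in (acc_e, acc_a, acc_c))
    summary = FractionSummary(f_E=f_e, f_A=f_a, f_C=f_c)
    return state, summary, bool(absorbed)
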