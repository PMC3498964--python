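"""Central executive: theory switches, paradigm specifications, condition
taxonomy and balanced trial-sequence generation.

Seven binary *semaphores* switch individual theory mechanisms on or off;
the five classic accounts of negative priming correspond to fixed rows of
the semaphore table (:func:`theory_preset`).  A paradigm maps stimuli onto
feature dimensions, semantic concepts and a response set; the sequence
generator builds a continuous chain of displays in which every trial primes
the next, with balanced priming conditions and target/distractor roles.
"""

from __future__ import annotations

import dataclasses
import random
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .dynamics import ConfigurationError

__all__ = [
    "TheoryWeights",
    "theory_preset",
    "THEORY_PRESETS",
    "StimulusObject",
    "Display",
    "Paradigm",
    "build_paradigm",
    "classify_condition",
    "generate_sequence",
    "CONDITIONS",
]

CONDITIONS = ("CO", "DT", "TT", "TD", "DD", "DDTT", "DTTD")


@dataclass(frozen=True)
class TheoryWeights:
    """Binary mechanism switches.

    xi_er : memory traces written (1) or no retrieval at all (0)
    xi_rr : full-state retrieval (1) or response-only retrieval (0)
    xi_ib : target boost (1) or distractor inhibition (0)
    xi_gt : activation broadening + forced decay on (1) / off (0)
    xi_fsb: retrieval blocks the feature->semantic synapses (1)
    xi_sab: retrieval blocks the semantic->action synapses (1)
    xi_td : old/new evaluation gates retrieval (1) or retrieval is
            similarity-scaled from trial onset (0)
    """

    xi_er: int = 0
    xi_rr: int = 0
    xi_ib: int = 0
    xi_gt: int = 0
    xi_fsb: int = 0
    xi_sab: int = 0
    xi_td: int = 0

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v not in (0, 1):
                raise ConfigurationError(f"semaphore {name} must be 0 or 1, got {v!r}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def as_tuple(self) -> tuple:
        return (self.xi_er, self.xi_rr, self.xi_ib, self.xi_gt,
                self.xi_fsb, self.xi_sab, self.xi_td)


THEORY_PRESETS = {
    "distractor_inhibition": TheoryWeights(0, 0, 0, 0, 0, 0, 0),
    "global_threshold": TheoryWeights(0, 0, 1, 1, 0, 0, 0),
    "episodic_retrieval": TheoryWeights(1, 1, 1, 0, 0, 0, 0),
    "response_retrieval": TheoryWeights(1, 0, 1, 0, 0, 0, 0),
    "temporal_discrimination": TheoryWeights(1, 1, 1, 0, 1, 1, 1),
}


def theory_preset(name: str) -> TheoryWeights:
    """Return the semaphore row for one of the five classic theories."""
    try:
        return THEORY_PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown theory preset {name!r}; valid names: {sorted(THEORY_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class StimulusObject:
    """One display object: a tuple of (dimension, label) feature instances."""

    features: tuple  # tuple of (dimension, label) pairs
    role: str        # "target" | "distractor" | "neutral"

    def __post_init__(self) -> None:
        dims = [d for d, _ in self.features]
        if len(set(dims)) != len(dims):
            raise ConfigurationError(f"object has duplicate dimensions: {self.features}")
        if self.role not in ("target", "distractor", "neutral"):
            raise ConfigurationError(f"invalid role {self.role!r}")

    def label(self, dimension: str) -> Optional[str]:
        for d, l in self.features:
            if d == dimension:
                return l
        return None


@dataclass(frozen=True)
class Display:
    """The stimulus content of one trial."""

    objects: tuple  # tuple of StimulusObject
    condition: Optional[str] = None          # label relative to the preceding display
    correct_response: Optional[str] = None   # comparison task: "yes" | "no"
    response_relation: Optional[str] = None  # comparison task: "s" | "r"

    @property
    def target(self) -> StimulusObject:
        return next(o for o in self.objects if o.role == "target")

    @property
    def distractor(self) -> StimulusObject:
        return next(o for o in self.objects if o.role == "distractor")


@dataclass(frozen=True)
class Paradigm:
    """Task specification: dimensions, mappings, response set and pool."""

    name: str
    kind: str                       # "naming" | "comparison"
    dimensions: tuple               # feature dimensions in use
    instances: dict                 # dimension -> tuple of labels
    concepts: tuple                 # semantic concepts
    actions: tuple                  # response set; actions[0] is always "a0"
    object_pool: tuple              # shape labels available for display objects
    target_defining: tuple          # (dimension, label), e.g. ("color", "green")
    distractor_defining: tuple      # (dimension, label)
    n_objects: int                  # objects per display (incl. the word, if any)

    @property
    def n_features_relevant(self) -> int:
        """#f — feature dimensions relevant to the task."""
        return len(self.dimensions)

    def instance_list(self) -> list:
        return [(d, l) for d in self.dimensions for l in self.instances[d]]

    # ------------------------------------------------------------------
    # display construction
    # ------------------------------------------------------------------
    def make_display(self, target_shape: str, distractor_shape: str,
                     word: Optional[str] = None, **annot) -> Display:
        if target_shape == distractor_shape:
            raise ConfigurationError("target and distractor must be distinct objects")
        for s in (target_shape, distractor_shape):
            if s not in self.object_pool:
                raise ConfigurationError(f"unknown object {s!r}")
        objs = [
            StimulusObject(((self.target_defining), ("shape", target_shape)), "target"),
            StimulusObject(((self.distractor_defining), ("shape", distractor_shape)), "distractor"),
        ]
        correct = annot.pop("correct_response", None)
        if self.kind == "comparison":
            if word is None:
                raise ConfigurationError("comparison paradigm requires a word")
            objs.append(StimulusObject((("word", word),), "neutral"))
            correct = "yes" if word == target_shape else "no"
        return Display(objects=tuple(objs), correct_response=correct, **annot)


_POOL = ("tree", "bus", "ball", "book", "bed", "bench")


def build_paradigm(name: str) -> Paradigm:
    """Construct one of the two shipped paradigms.

    ``voicekey``     — name the green pictogram aloud; the semantic layer is a
                       one-to-one copy of the shape layer, one naming action
                       per object.
    ``word_picture`` — decide whether the displayed word names the green
                       picture; responses are yes/no, so target identity and
                       response are decoupled and the response relation
                       (switch ``s`` / repeat ``r``) becomes a second factor.
    """
    if name == "voicekey":
        return Paradigm(
            name="voicekey",
            kind="naming",
            dimensions=("color", "shape"),
            instances={"color": ("green", "red"), "shape": _POOL},
            concepts=_POOL,
            actions=("a0",) + tuple(f"name:{s}" for s in _POOL),
            object_pool=_POOL,
            target_defining=("color", "green"),
            distractor_defining=("color", "red"),
            n_objects=2,
        )
    if name == "word_picture":
        return Paradigm(
            name="word_picture",
            kind="comparison",
            dimensions=("color", "shape", "word"),
            instances={"color": ("green", "red"), "shape": _POOL, "word": _POOL},
            concepts=_POOL,
            actions=("a0", "yes", "no"),
            object_pool=_POOL,
            target_defining=("color", "green"),
            distractor_defining=("color", "red"),
            n_objects=3,
        )
    raise ConfigurationError(f"unknown paradigm {name!r}; valid: voicekey, word_picture")


def classify_condition(prime: Display, probe: Display) -> str:
    """Label the probe display relative to its prime.

    First letter: role of the repeated object in the prime (T/D); second:
    its role in the probe.  CO if nothing repeats, DDTT/DTTD when both
    objects repeat in the same/swapped roles.
    """
    tp, dp = prime.target.label("shape"), prime.distractor.label("shape")
    t, d = probe.target.label("shape"), probe.distractor.label("shape")
    if tp is None or dp is None or t is None or d is None or tp == dp or t == d:
        raise ConfigurationError("displays must each carry one target and one distractor")
    if t == tp and d == dp:
        return "DDTT"
    if t == dp and d == tp:
        return "DTTD"
    if t == tp:
        return "TT"
    if t == dp:
        return "DT"
    if d == tp:
        return "TD"
    if d == dp:
        return "DD"
    return "CO"


def _split_label(label: str) -> tuple:
    """'DTs' -> ('DT', 's'); 'CO' -> ('CO', None)."""
    if label.endswith(("s", "r")) and label[:-1] in CONDITIONS:
        return label[:-1], label[-1]
    if label in CONDITIONS:
        return label, None
    raise ConfigurationError(f"unknown condition label {label!r}")


def _choose(rng: random.Random, candidates: Sequence[str], scores: dict) -> str:
    """Pick a candidate with minimal balance score, seeded tie-break."""
    best = min(scores[c] for c in candidates)
    pool = [c for c in candidates if scores[c] == best]
    return pool[rng.randrange(len(pool))]


def generate_sequence(paradigm: Paradigm, conditions: Iterable[str],
                      n_per_condition: int, seed: int) -> list:
    """Generate a continuous display chain with balanced conditions and roles.

    Returns ``1 + n_conditions * n_per_condition`` displays: a lead-in
    display followed by one classified probe per requested condition
    occurrence (each display is simultaneously the prime of the next).
    Every object's target-appearance count stays within +/-1 of its
    distractor-appearance count.  Deterministic for a fixed seed.
    """
    conditions = list(conditions)
    if n_per_condition < 1 or not conditions:
        raise ConfigurationError("need at least one condition occurrence")
    if len(paradigm.object_pool) < 4:
        raise ConfigurationError(
            "object pool too small for CO construction: need >= 4 objects "
            f"(have {len(paradigm.object_pool)})"
        )
    last_err = None
    for attempt in range(64):
        rng = random.Random((seed, attempt).__hash__() & 0x7FFFFFFF)
        try:
            seq = _generate_once(paradigm, conditions, n_per_condition, rng)
        except ConfigurationError as err:  # pragma: no cover - retry path
            last_err = err
            continue
        if _roles_balanced(seq):
            return seq
    if last_err is not None:  # pragma: no cover
        raise last_err
    raise ConfigurationError(
        "could not balance target/distractor roles within +/-1 per object; "
        "try more trials per condition or a different seed"
    )


def _generate_once(paradigm: Paradigm, conditions: list, n_per_condition: int,
                   rng: random.Random) -> list:
    order = [c for c in conditions for _ in range(n_per_condition)]
    rng.shuffle(order)
    pool = list(paradigm.object_pool)
    t_cnt = {o: 0 for o in pool}
    d_cnt = {o: 0 for o in pool}

    def t_score(o):  # want objects that lag in target appearances
        return t_cnt[o] - d_cnt[o]

    def d_score(o):
        return d_cnt[o] - t_cnt[o]

    def count(t, d):
        t_cnt[t] += 1
        d_cnt[d] += 1

    # lead-in display
    t0 = _choose(rng, pool, {o: t_score(o) for o in pool})
    d0 = _choose(rng, [o for o in pool if o != t0], {o: d_score(o) for o in pool})
    count(t0, d0)
    prev_t, prev_d = t0, d0
    prev_response = "yes"
    displays = []
    if paradigm.kind == "comparison":
        displays.append(paradigm.make_display(t0, d0, word=t0))
    else:
        displays.append(paradigm.make_display(t0, d0))

    for label in order:
        cond, relation = _split_label(label)
        if relation is not None and paradigm.kind != "comparison":
            raise ConfigurationError(
                f"response-relation suffix in {label!r} requires the comparison paradigm"
            )
        fresh = [o for o in pool if o not in (prev_t, prev_d)]
        if cond == "DDTT":
            t, d = prev_t, prev_d
        elif cond == "DTTD":
            t, d = prev_d, prev_t
        elif cond == "TT":
            t = prev_t
            d = _choose(rng, fresh, {o: d_score(o) for o in fresh})
        elif cond == "DT":
            t = prev_d
            d = _choose(rng, fresh, {o: d_score(o) for o in fresh})
        elif cond == "TD":
            d = prev_t
            t = _choose(rng, fresh, {o: t_score(o) for o in fresh})
        elif cond == "DD":
            d = prev_d
            t = _choose(rng, fresh, {o: t_score(o) for o in fresh})
        else:  # CO
            t = _choose(rng, fresh, {o: t_score(o) for o in fresh})
            rest = [o for o in fresh if o != t]
            d = _choose(rng, rest, {o: d_score(o) for o in rest})
        count(t, d)

        if paradigm.kind == "comparison":
            if relation is None:
                relation = "s" if rng.random() < 0.5 else "r"
            want = prev_response if relation == "r" else ("no" if prev_response == "yes" else "yes")
            if want == "yes":
                word = t
            else:
                off_display = [o for o in pool if o not in (t, d)]
                word = off_display[rng.randrange(len(off_display))]
            disp = paradigm.make_display(t, d, word=word,
                                         condition=cond + relation,
                                         response_relation=relation)
            prev_response = disp.correct_response
        else:
            disp = paradigm.make_display(t, d, condition=cond)
        displays.append(disp)
        prev_t, prev_d = t, d
    return displays


def _roles_balanced(displays: list) -> bool:
    t_cnt: dict = {}
    d_cnt: dict = {}
    for disp in displays:
        t_cnt[disp.target.label("shape")] = t_cnt.get(disp.target.label("shape"), 0) + 1
        d_cnt[disp.distractor.label("shape")] = d_cnt.get(disp.distractor.label("shape"), 0) + 1
    objects = set(t_cnt) | set(d_cnt)
    return all(abs(t_cnt.get(o, 0) - d_cnt.get(o, 0)) <= 1 for o in objects)
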