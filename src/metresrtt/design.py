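"""Experimental design for a metre-augmented serial reaction time task (SRTT).

The visual sequence is a 12-unit, equal-frequency, equal-transition series
over four cue locations.  Read cyclically, such a sequence is exactly an
Eulerian circuit on the complete directed graph over the four locations
(every ordered pair of distinct locations used once as a transition), which
is how sequences are constructed and enumerated here.

An auditory metre (grouping of 3 or 4 beats, one accented beat per group,
60 bpm with a faster background subdivision) runs alongside the visual
sequence; this module builds the accent schedules, the 12-block plan with
its phase-shifted and new-metre test blocks, and the same/different rhythm
discrimination stimuli used to score rhythmic sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

LOCATIONS = (1, 2, 3, 4)
SEQUENCE_LENGTH = 12
CUES_PER_BLOCK = 120
N_CYCLES = 10
BEAT_IOI_MS = 1000

#: The two spatial cue -> response key bijections used for counterbalancing.
#: Under mapping A the locations 3-1-4-2 read N-Z-M-X; under B, Z-N-X-M.
KEY_MAPPING_A = {1: "Z", 2: "X", 3: "N", 4: "M"}
KEY_MAPPING_B = {1: "N", 2: "M", 3: "Z", 4: "X"}

#: Inter-onset intervals (ms) whose re-orderings form the rhythm
#: discrimination patterns: nine conga strikes spanning 3.2 s.
RHYTHM_IOI_MULTISET = (200, 200, 200, 200, 200, 400, 400, 600, 800)

BLOCK_ROLES = ("learning",) * 8 + ("phase_shifted", "learning", "new_metre", "new_visual")


@dataclass(frozen=True)
class SequenceDesign:
    """A 12-element cue-location series satisfying the transition constraints."""

    locations: tuple[int, ...]
    label: str = ""

    def __post_init__(self):
        report = validate_sequence(self.locations)
        if not report.valid:
            raise ValueError(f"invalid sequence {self.locations}: {report.violations}")


@dataclass(frozen=True)
class ValidityReport:
    valid: bool
    violations: tuple[str, ...]


@dataclass(frozen=True)
class MetreSchedule:
    """Accent grid of one metric cycle at 60 bpm plus its subdivision."""

    grouping: int
    accent_pattern: tuple[int, ...]
    beat_ioi_ms: int
    subdivisions_per_beat: int
    subdivision_ioi_ms: int


@dataclass(frozen=True)
class BlockSpec:
    index: int
    role: str
    start_offset: int
    n_cycles: int
    metre_grouping: int
    accent_shift: int


@dataclass
class TaskDesign:
    """One counterbalanced realisation of the task for a single participant."""

    sequence: SequenceDesign
    novel_sequence: SequenceDesign
    mapping: dict[int, str]
    metre_condition: int
    blocks: list[BlockSpec]
    accent_by_cue: tuple[int, ...]
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "sequence": list(self.sequence.locations),
            "sequence_label": self.sequence.label,
            "novel_sequence": list(self.novel_sequence.locations),
            "novel_sequence_label": self.novel_sequence.label,
            "mapping": {str(k): v for k, v in self.mapping.items()},
            "metre_condition": self.metre_condition,
            "accent_by_cue": list(self.accent_by_cue),
            "blocks": [asdict(b) for b in self.blocks],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskDesign":
        return cls(
            sequence=SequenceDesign(tuple(d["sequence"]), d.get("sequence_label", "")),
            novel_sequence=SequenceDesign(
                tuple(d["novel_sequence"]), d.get("novel_sequence_label", "")
            ),
            mapping={int(k): v for k, v in d["mapping"].items()},
            metre_condition=int(d["metre_condition"]),
            blocks=[BlockSpec(**b) for b in d["blocks"]],
            accent_by_cue=tuple(d["accent_by_cue"]),
            label=d.get("label", ""),
        )


@dataclass(frozen=True)
class RhythmTrial:
    pattern_a: tuple[int, ...]
    pattern_b: tuple[int, ...]
    same: bool
    difficulty: str  # "easier" | "harder"; meaningful for different trials


# ---------------------------------------------------------------------------
# Sequences


def validate_sequence(candidate: Sequence[int]) -> ValidityReport:
    """Check the four constraints defining a valid 12-unit cue sequence.

    Constraints, with the sequence read cyclically (last -> first included):
    length 12; each location three times; all 12 ordered transitions between
    distinct locations exactly once; no element equal to its cyclic successor.
    """
    candidate = list(candidate)
    if len(candidate) == 0:
        raise ValueError("empty sequence")
    bad = [x for x in candidate if x not in LOCATIONS]
    if bad:
        raise ValueError(f"location indices must be in 1..4, got {sorted(set(bad))}")

    violations: list[str] = []
    if len(candidate) != SEQUENCE_LENGTH:
        violations.append(f"wrong length: {len(candidate)} != {SEQUENCE_LENGTH}")
    counts = {loc: candidate.count(loc) for loc in LOCATIONS}
    if any(c != 3 for c in counts.values()):
        violations.append(f"unequal location frequencies: {counts}")

    transitions = [
        (candidate[i], candidate[(i + 1) % len(candidate)]) for i in range(len(candidate))
    ]
    if any(a == b for a, b in transitions):
        violations.append("element equal to its cyclic successor")
    required = {(a, b) for a in LOCATIONS for b in LOCATIONS if a != b}
    seen: dict[tuple[int, int], int] = {}
    for t in transitions:
        seen[t] = seen.get(t, 0) + 1
    repeated = sorted(t for t, n in seen.items() if n > 1 and t[0] != t[1])
    missing = sorted(required - set(seen))
    if repeated:
        violations.append(
            "repeated transitions: "
            + ", ".join(f"{a}->{b} occurs {seen[(a, b)]} times" for a, b in repeated)
        )
    if missing and len(candidate) == SEQUENCE_LENGTH:
        violations.append("missing transitions: " + ", ".join(f"{a}->{b}" for a, b in missing))

    return ValidityReport(valid=not violations, violations=tuple(violations))


def _eulerian_circuits(start: int) -> list[tuple[int, ...]]:
    """All Eulerian circuits of the complete digraph on 4 nodes from `start`.

    Each circuit is returned as its 12-node visiting order (the cue list);
    the closing arc back to `start` is implicit.
    """
    arcs = {(a, b) for a in LOCATIONS for b in LOCATIONS if a != b}
    out: list[tuple[int, ...]] = []

    def walk(node: int, path: list[int], used: set[tuple[int, int]]):
        if len(path) == SEQUENCE_LENGTH:
            if (node, start) in arcs and (node, start) not in used:
                # all 12 arcs used exactly once only if the closing arc is free
                if len(used) == SEQUENCE_LENGTH - 1:
                    out.append(tuple(path))
            return
        for nxt in LOCATIONS:
            if nxt != node and (node, nxt) not in used:
                used.add((node, nxt))
                path.append(nxt)
                walk(nxt, path, used)
                path.pop()
                used.remove((node, nxt))

    walk(start, [start], set())
    return out


@lru_cache(maxsize=1)
def enumerate_basic_sequences() -> tuple[tuple[int, ...], ...]:
    """Exhaustively enumerate every valid 12-element sequence.

    Rotations count as distinct lists.  The pool is the set of Eulerian
    circuits of the complete 4-node digraph, read as node sequences.
    """
    pool: list[tuple[int, ...]] = []
    for start in LOCATIONS:
        pool.extend(_eulerian_circuits(start))
    return tuple(sorted(set(pool)))


def generate_basic_sequence(seed: int) -> SequenceDesign:
    """Seeded backtracking Eulerian-circuit search; deterministic per seed."""
    rng = np.random.default_rng(seed)
    start = int(rng.choice(LOCATIONS))
    arcs_left = {(a, b) for a in LOCATIONS for b in LOCATIONS if a != b}

    def walk(node: int, path: list[int]) -> list[int] | None:
        if len(path) == SEQUENCE_LENGTH:
            return path if (node, start) in arcs_left else None
        nxts = [n for n in LOCATIONS if n != node and (node, n) in arcs_left]
        rng.shuffle(nxts)
        for nxt in nxts:
            arcs_left.remove((node, nxt))
            found = walk(nxt, path + [nxt])
            if found is not None:
                return found
            arcs_left.add((node, nxt))
        return None

    path = walk(start, [start])
    assert path is not None  # Eulerian circuits always exist on this graph
    return SequenceDesign(tuple(path), label=f"seed{seed}")


# ---------------------------------------------------------------------------
# Metre and blocks


def build_metre_schedule(grouping: int) -> MetreSchedule:
    """Accent pattern, beat and subdivision timing for a 3- or 4-grouping."""
    if grouping not in (3, 4):
        raise ValueError(f"grouping must be 3 or 4, got {grouping}")
    subdivision = 333 if grouping == 3 else 250
    return MetreSchedule(
        grouping=grouping,
        accent_pattern=(1,) + (0,) * (grouping - 1),
        beat_ioi_ms=BEAT_IOI_MS,
        subdivisions_per_beat=grouping,
        subdivision_ioi_ms=subdivision,
    )


def accent_flags(grouping: int, shift: int = 0) -> tuple[int, ...]:
    """Accent flag for each of the 12 cue positions of the super-cycle.

    Position p is accented iff ``(p - 1 - shift) mod grouping == 0``; a shift
    of 1 delays the accent pattern by one cue step.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    pattern = build_metre_schedule(grouping).accent_pattern
    return tuple(pattern[(p - 1 - shift) % grouping] for p in range(1, SEQUENCE_LENGTH + 1))


def assign_accents(design: TaskDesign, shift: int) -> tuple[int, ...]:
    """Accent flags over the 12 cue positions of `design` under a phase shift."""
    return accent_flags(design.metre_condition, shift)


def build_block_plan(metre_condition: int, seed: int) -> list[BlockSpec]:
    """The fixed 12-block order: 8 learning, phase-shifted, learning,
    new-metre, new-visual; start offsets sampled without replacement."""
    if metre_condition not in (3, 4):
        raise ValueError(f"metre_condition must be 3 or 4, got {metre_condition}")
    rng = np.random.default_rng(seed)
    offsets = rng.permutation(np.arange(1, SEQUENCE_LENGTH + 1))
    other = 7 - metre_condition
    blocks = []
    for i, role in enumerate(BLOCK_ROLES, start=1):
        blocks.append(
            BlockSpec(
                index=i,
                role=role,
                start_offset=int(offsets[i - 1]),
                n_cycles=N_CYCLES,
                metre_grouping=other if role == "new_metre" else metre_condition,
                accent_shift=1 if role == "phase_shifted" else 0,
            )
        )
    return blocks


def build_task_design(
    sequence: SequenceDesign,
    mapping: dict[int, str],
    metre_condition: int,
    seed: int,
    novel_sequence: SequenceDesign | None = None,
    label: str = "",
) -> TaskDesign:
    """Assemble a full TaskDesign, drawing a novel block-12 sequence that
    differs from the learned one in at least 6 cyclic positions."""
    rng = np.random.default_rng(seed)
    if novel_sequence is None:
        pool = enumerate_basic_sequences()
        order = rng.permutation(len(pool))
        for idx in order:
            cand = pool[idx]
            if sum(a != b for a, b in zip(cand, sequence.locations)) >= 6:
                novel_sequence = SequenceDesign(cand, label="novel")
                break
        assert novel_sequence is not None
    blocks = build_block_plan(metre_condition, int(rng.integers(2**31)))
    return TaskDesign(
        sequence=sequence,
        novel_sequence=novel_sequence,
        mapping=dict(mapping),
        metre_condition=metre_condition,
        blocks=blocks,
        accent_by_cue=accent_flags(metre_condition, 0),
        label=label,
    )


def build_counterbalance(seed: int, metre_condition: int = 4) -> list[TaskDesign]:
    """Six distinct sequence structures x two key mappings = 12 variants."""
    pool = enumerate_basic_sequences()
    if len(pool) < 6:
        raise ValueError("valid-sequence pool smaller than 6")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=6, replace=False)
    variants = []
    for si, idx in enumerate(chosen):
        seq = SequenceDesign(pool[idx], label=f"S{si + 1}")
        for mi, mapping in enumerate((KEY_MAPPING_A, KEY_MAPPING_B)):
            variants.append(
                build_task_design(
                    seq,
                    mapping,
                    metre_condition,
                    seed=int(rng.integers(2**31)),
                    label=f"S{si + 1}{'AB'[mi]}",
                )
            )
    return variants


# ---------------------------------------------------------------------------
# Rhythm discrimination stimuli


def _random_pattern(rng: np.random.Generator) -> tuple[int, ...]:
    iois = np.array(RHYTHM_IOI_MULTISET)
    return tuple(int(x) for x in rng.permutation(iois))


def generate_rhythm_trial(seed: int, same: bool, difficulty: str = "easier") -> RhythmTrial:
    """One same/different trial over the fixed nine-interval multiset.

    Difficulty of "different" trials is operationalised by the length of the
    shared IOI prefix: easier pairs diverge within the first 3 intervals,
    harder pairs agree on at least the first 4.
    """
    if difficulty not in ("easier", "harder"):
        raise ValueError(f"difficulty must be 'easier' or 'harder', got {difficulty!r}")
    rng = np.random.default_rng(seed)
    a = _random_pattern(rng)
    if same:
        return RhythmTrial(a, a, True, difficulty)
    min_prefix, max_prefix = (4, 7) if difficulty == "harder" else (0, 2)
    while True:
        b = _random_pattern(rng)
        if b == a:
            continue
        prefix = 0
        while prefix < len(a) and a[prefix] == b[prefix]:
            prefix += 1
        if min_prefix <= prefix <= max_prefix:
            return RhythmTrial(a, b, False, difficulty)


def build_rhythm_session(seed: int) -> list[RhythmTrial]:
    """Forty trials: 20 same, 10 easier-different, 10 harder-different, with
    easier "different" trials concentrated in the first half."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=40)
    trials = (
        [generate_rhythm_trial(int(s), same=True) for s in seeds[:20]]
        + [generate_rhythm_trial(int(s), same=False, difficulty="easier") for s in seeds[20:30]]
        + [generate_rhythm_trial(int(s), same=False, difficulty="harder") for s in seeds[30:40]]
    )
    same_trials, easier, harder = trials[:20], trials[20:30], trials[30:40]
    # 8 of 10 easier-different trials in the first half, 8 of 10 harder in
    # the second, padded with "same" trials; seeded shuffle within halves.
    first = easier[:8] + harder[:2] + same_trials[:10]
    second = easier[8:] + harder[2:] + same_trials[10:]
    rng.shuffle(first)
    rng.shuffle(second)
    return first + second


# ---------------------------------------------------------------------------
# Export


def _block_accent_flags(block: BlockSpec) -> tuple[int, ...]:
    return accent_flags(block.metre_grouping, block.accent_shift)


def design_to_frame(design: TaskDesign, participant: str = "P1") -> pd.DataFrame:
    """One row per scheduled cue across all 12 blocks.

    ``position_in_cycle`` is the position within the 12-cue visual sequence;
    each block starts at its own offset and wraps cyclically.  ``onset_ms``
    is cumulative from block start at the 1000 ms beat spacing.
    """
    key_lut = np.array(["?"] + [design.mapping[loc] for loc in range(1, 5)])
    frames = []
    for block in design.blocks:
        seq = np.array(
            design.novel_sequence.locations
            if block.role == "new_visual"
            else design.sequence.locations
        )
        flags = np.array(_block_accent_flags(block))
        n_cues = SEQUENCE_LENGTH * block.n_cycles
        i = np.arange(n_cues)
        pos = (block.start_offset - 1 + i) % SEQUENCE_LENGTH + 1
        loc = seq[pos - 1]
        frames.append(
            pd.DataFrame(
                {
                    "participant": participant,
                    "block": block.index,
                    "role": block.role,
                    "cycle": i // SEQUENCE_LENGTH + 1,
                    "position_in_cycle": pos,
                    "cue_location": loc,
                    "response_key": key_lut[loc],
                    "accent": flags[pos - 1],
                    "onset_ms": i * BEAT_IOI_MS,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_design_json(design: TaskDesign, path) -> None:
    with open(path, "w") as fh:
        json.dump(design.to_dict(), fh, indent=1)


def read_design_json(path) -> TaskDesign:
    with open(path) as fh:
        return TaskDesign.from_dict(json.load(fh))
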