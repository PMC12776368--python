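"""Task-sequence generation for the single-exposure visual memory task.

Each image is shown exactly twice: once as *novel* and later as *repeated*,
separated by ``n_back`` intervening trials.  Sequences are scheduled so that
realized n-backs are drawn as uniformly as packing permits from a requested
set; pairs that cannot be placed at a requested n-back are scheduled at the
nearest free slot and flagged as fillers.

The trial table is a :class:`pandas.DataFrame` with the columns listed in
:data:`TRIAL_COLUMNS`; :func:`validate_trial_table` checks its invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "CategorySpec",
    "InfeasiblePackingError",
    "generate_task_sequence",
    "validate_trial_table",
]

#: Canonical column order of a trial table.
TRIAL_COLUMNS = [
    "trial_index",
    "image_id",
    "exposure",
    "n_back",
    "memorability",
    "category",
    "block_id",
    "choice",
    "session_id",
    "is_filler",
]


class InfeasiblePackingError(ValueError):
    """Raised when a requested n-back cannot be scheduled at all."""


@dataclass(frozen=True)
class CategorySpec:
    """Blocked category structure of the categorical task variant.

    Trials are organized into equally sized blocks.  In a *categorical*
    block a fixed majority fraction of images is drawn from that block's
    majority category (majority categories cycle through ``categories``);
    the remainder is drawn uniformly from the other categories.  Blocks
    listed in ``random_blocks`` draw every image uniformly.
    """

    categories: Sequence[str] = ("animals", "faces", "fruits", "objects", "places")
    n_blocks: int = 5
    majority_fraction: float = 0.8
    random_blocks: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.majority_fraction <= 1.0:
            raise ValueError("majority_fraction must lie in [0, 1]")
        if len(self.categories) < 2:
            raise ValueError("need at least two categories")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be positive")


def _schedule_pairs(
    n_images: int, n_backs: Sequence[int], rng: np.random.Generator
) -> list[tuple[int, int, int, bool]]:
    """Greedy pair placement.

    Returns ``(novel_slot, repeated_slot, n_back, is_filler)`` per image.
    Target n-backs are assigned to images as uniformly as possible and the
    sequence is filled front to back, preferring on-target placements.
    """
    n_backs = sorted(set(int(n) for n in n_backs))
    if not n_backs:
        raise ValueError("n_backs must be non-empty")
    if min(n_backs) < 1:
        raise ValueError("n-backs must be positive integers")
    n_trials = 2 * n_images
    if n_images < max(n_backs) + 1:
        raise InfeasiblePackingError(
            f"n-back {max(n_backs)} cannot be scheduled with only "
            f"{n_images} images (need at least {max(n_backs) + 1})"
        )

    # desired n-backs, as uniform as divisibility allows, in random order
    desired = np.array([n_backs[i % len(n_backs)] for i in range(n_images)])
    rng.shuffle(desired)

    occupied = np.zeros(n_trials, dtype=bool)
    queue: list[int] = list(range(n_images))  # image indices awaiting placement
    placements: dict[int, tuple[int, int, int, bool]] = {}

    for t in range(n_trials):
        if occupied[t]:
            continue
        if not queue:
            break
        placed = False
        for qi, img in enumerate(queue):
            rep = t + int(desired[img]) + 1
            if rep < n_trials and not occupied[rep]:
                occupied[t] = occupied[rep] = True
                placements[img] = (t, rep, int(desired[img]), False)
                queue.pop(qi)
                placed = True
                break
        if not placed:
            # filler: nearest free slot after t
            img = queue.pop(0)
            free = np.flatnonzero(~occupied[t + 1 :])
            rep = t + 1 + int(free[0])
            occupied[t] = occupied[rep] = True
            placements[img] = (t, rep, rep - t - 1, True)

    realized_on_target = {n: 0 for n in n_backs}
    for _, (_, _, nb, filler) in placements.items():
        if not filler and nb in realized_on_target:
            realized_on_target[nb] += 1
    for n, count in realized_on_target.items():
        if count == 0:
            raise InfeasiblePackingError(
                f"requested n-back {n} could not be scheduled in a "
                f"{n_trials}-trial sequence"
            )
    return [placements[i] for i in range(n_images)]


def _sample_memorability(
    sampler: Callable[[np.random.Generator, int], np.ndarray] | None,
    rng: np.random.Generator,
    n: int,
) -> np.ndarray:
    if sampler is None:
        mem = rng.uniform(0.0, 1.0, size=n)
    else:
        mem = np.asarray(sampler(rng, n), dtype=float)
    if mem.shape != (n,) or np.any(mem < 0) or np.any(mem > 1):
        raise ValueError("memorability sampler must return n values in [0, 1]")
    return mem


def generate_task_sequence(
    n_images: int,
    n_backs: Sequence[int],
    memorability_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    category_spec: CategorySpec | None = None,
    seed: int = 0,
    session_id: str = "sim",
) -> pd.DataFrame:
    """Generate a trial table for one session.

    Parameters
    ----------
    n_images
        Number of distinct images; the sequence has ``2 * n_images`` trials.
        With a ``category_spec`` this must be divisible by its ``n_blocks``
        and pairs are scheduled within blocks (an image never spans blocks).
    n_backs
        Target set of n-backs (intervening-trial counts).
    memorability_sampler
        ``f(rng, n) -> array in [0, 1]``; defaults to uniform.
    """
    rng = np.random.default_rng(seed)
    if n_images < 1:
        raise ValueError("n_images must be positive")

    if category_spec is None:
        block_sizes = [n_images]
    else:
        if n_images % category_spec.n_blocks:
            raise ValueError("n_images must be divisible by category_spec.n_blocks")
        block_sizes = [n_images // category_spec.n_blocks] * category_spec.n_blocks

    rows: list[dict] = []
    img_counter = 0
    trial_offset = 0
    for block_id, block_images in enumerate(block_sizes):
        pairs = _schedule_pairs(block_images, n_backs, rng)
        mem = _sample_memorability(memorability_sampler, rng, block_images)
        if category_spec is None:
            cats = [None] * block_images
        else:
            cats = _draw_block_categories(category_spec, block_id, block_images, rng)
        for i, (nov, rep, nb, filler) in enumerate(pairs):
            image_id = f"{session_id}_img{img_counter + i:05d}"
            common = dict(
                image_id=image_id,
                n_back=nb,
                memorability=float(mem[i]),
                category=cats[i],
                block_id=block_id,
                choice="none",
                session_id=session_id,
                is_filler=filler,
            )
            rows.append(dict(trial_index=trial_offset + nov, exposure="novel", **common))
            rows.append(dict(trial_index=trial_offset + rep, exposure="repeated", **common))
        img_counter += block_images
        trial_offset += 2 * block_images

    table = pd.DataFrame(rows).sort_values("trial_index").reset_index(drop=True)
    return table[TRIAL_COLUMNS]


def _draw_block_categories(
    spec: CategorySpec, block_id: int, n: int, rng: np.random.Generator
) -> list[str]:
    cats = list(spec.categories)
    if block_id in spec.random_blocks:
        return [cats[i] for i in rng.integers(0, len(cats), size=n)]
    majority = cats[block_id % len(cats)]
    others = [c for c in cats if c != majority]
    out = []
    for _ in range(n):
        if rng.uniform() < spec.majority_fraction:
            out.append(majority)
        else:
            out.append(others[rng.integers(0, len(others))])
    return out


def validate_trial_table(table: pd.DataFrame) -> None:
    """Check the structural invariants of a trial table; raise on violation.

    Every image appears exactly twice (novel before repeated), the trial gap
    between the pair equals ``n_back + 1``, and memorability is identical on
    both rows of a pair.
    """
    for col in TRIAL_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    counts = table.groupby("image_id").size()
    if not (counts == 2).all():
        bad = counts[counts != 2].index.tolist()
        raise ValueError(f"images not shown exactly twice: {bad[:5]}")
    for image_id, grp in table.groupby("image_id"):
        by_exp = grp.set_index("exposure")
        if set(by_exp.index) != {"novel", "repeated"}:
            raise ValueError(f"{image_id}: need one novel and one repeated row")
        nov, rep = by_exp.loc["novel"], by_exp.loc["repeated"]
        if not nov["trial_index"] < rep["trial_index"]:
            raise ValueError(f"{image_id}: novel must precede repeated")
        gap = int(rep["trial_index"]) - int(nov["trial_index"]) - 1
        if gap != int(rep["n_back"]):
            raise ValueError(f"{image_id}: trial gap {gap} != n_back {rep['n_back']}")
        if nov["memorability"] != rep["memorability"]:
            raise ValueError(f"{image_id}: memorability differs across the pair")
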