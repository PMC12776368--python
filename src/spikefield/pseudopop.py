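"""Pseudopopulation alignment across sessions.

Sessions recorded on different days are aligned into one population by
pairing images with matched task conditions: trials are narrowed to valid
image pairs at target n-backs, images are grouped by n-back (or category,
for the categorical task) and ordered by memorability, richer sessions are
subsampled linearly across the memorability ranking, and the k-th ranked
image of each session in a group is merged into one *pseudoimage*.  Both
measures (unit spike counts and channel band responses) are carried for
every pseudoimage, and a channel serving several sorted units appears once
per unit so that spike- and field-based populations have matched sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import SessionData

__all__ = [
    "Pseudopopulation",
    "filter_trials",
    "memorability_subsample",
    "build_pseudopopulation",
]

log = logging.getLogger(__name__)


@dataclass
class Pseudopopulation:
    """Image-aligned response matrices for novel and repeated presentations.

    ``spikes_*`` and ``channels_*`` are observation x pseudoimage matrices
    with matched columns; the channel matrices have one row per *unit* (a
    channel with several sorted units contributes one identical row per
    unit, so populations of the two measures have matched sizes).
    """

    images: pd.DataFrame  # per pseudoimage: n_back, memorability, category
    spikes_novel: np.ndarray
    spikes_repeated: np.ndarray
    channels_novel: np.ndarray
    channels_repeated: np.ndarray
    observations: pd.DataFrame  # per row: session, unit, channel
    analysis_window_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        shapes = {
            m.shape
            for m in (
                self.spikes_novel,
                self.spikes_repeated,
                self.channels_novel,
                self.channels_repeated,
            )
        }
        if len(shapes) != 1:
            raise ValueError(f"response matrices disagree in shape: {shapes}")
        if self.spikes_novel.shape[1] != len(self.images):
            raise ValueError("column count must match number of pseudoimages")
        if self.spikes_novel.shape[0] != len(self.observations):
            raise ValueError("row count must match observation metadata")

    @property
    def n_observations(self) -> int:
        return int(self.spikes_novel.shape[0])

    @property
    def n_images(self) -> int:
        return int(self.spikes_novel.shape[1])

    def responses(self, measure: str) -> tuple[np.ndarray, np.ndarray]:
        """(novel, repeated) matrices for ``measure`` in {'spikes', 'channels'}."""
        if measure == "spikes":
            return self.spikes_novel, self.spikes_repeated
        if measure == "channels":
            return self.channels_novel, self.channels_repeated
        raise ValueError("measure must be 'spikes' or 'channels'")


def filter_trials(trials: pd.DataFrame, target_n_backs: Sequence[int]) -> pd.DataFrame:
    """Keep only images whose novel AND repeated rows are both usable.

    Usable means: at a target n-back, not a scheduling filler, and with a
    behavioral report on both rows (``choice != 'none'``).  Both rows of a
    surviving image are kept; an empty result is returned with a warning.
    """
    targets = set(int(n) for n in target_n_backs)
    keep = []
    for image_id, g in trials.groupby("image_id"):
        if len(g) != 2:
            continue
        if int(g["n_back"].iloc[0]) not in targets:
            continue
        if "is_filler" in g and bool(g["is_filler"].any()):
            continue
        if (g["choice"] == "none").any():
            continue
        keep.append(image_id)
    out = trials[trials["image_id"].isin(keep)].reset_index(drop=True)
    if out.empty:
        warnings.warn("no images survive trial filtering", stacklevel=2)
    return out


def memorability_subsample(ranked_image_ids: Sequence, k: int) -> list:
    """Select ``k`` of ``m`` memorability-ranked images linearly across ranks.

    Positions are ``round(linspace(1, m, k))`` in the ranked list (1-based),
    spanning the full memorability range; duplicates are impossible for
    ``k <= m`` because successive positions are at least one rank apart.
    """
    m = len(ranked_image_ids)
    if not 1 <= k <= m:
        raise ValueError(f"k must lie in [1, {m}], got {k}")
    ranks = np.floor(np.linspace(1.0, float(m), k) + 0.5).astype(int)
    return [ranked_image_ids[r - 1] for r in ranks]


def _image_table(session: SessionData) -> pd.DataFrame:
    """One row per image: condition metadata plus the trial-array column
    indices of its novel and repeated presentations."""
    t = session.trial_table.reset_index(drop=True)
    nov = t[t["exposure"] == "novel"]
    rep = t[t["exposure"] == "repeated"]
    nov = nov.set_index("image_id")
    rep = rep.set_index("image_id")
    if set(nov.index) != set(rep.index):
        raise ValueError("trial table image pairs are incomplete")
    imgs = pd.DataFrame(
        {
            "n_back": rep["n_back"].astype(int),
            "memorability": rep["memorability"].astype(float),
            "category": rep["category"] if "category" in rep else pd.NA,
        }
    )
    # positional indices in the original trial order = trial-array columns
    positions = {img: {} for img in imgs.index}
    for pos, row in t.iterrows():
        positions[row["image_id"]][row["exposure"]] = pos
    imgs["novel_col"] = [positions[i]["novel"] for i in imgs.index]
    imgs["repeated_col"] = [positions[i]["repeated"] for i in imgs.index]
    if "is_filler" in t:
        filler = t.groupby("image_id")["is_filler"].any()
        imgs["is_filler"] = filler.reindex(imgs.index).fillna(False)
    else:
        imgs["is_filler"] = False
    if "choice" in t:
        reported = t.groupby("image_id")["choice"].apply(lambda c: (c != "none").all())
        imgs["reported"] = reported.reindex(imgs.index)
    else:
        imgs["reported"] = True
    return imgs


def build_pseudopopulation(
    sessions: Sequence[SessionData],
    band_responses: Sequence[np.ndarray],
    target_n_backs: Sequence[int],
    analysis_window_ms: tuple[float, float] | None = None,
    require_choice: bool = False,
    group_by: str = "n_back",
) -> Pseudopopulation:
    """Align sessions into a pseudopopulation.

    Parameters
    ----------
    sessions
        Sessions providing unit spike counts and trial tables.
    band_responses
        Per session, a (n_channels, n_trials) array of the channel measure
        (HGA percent change, or the rate-mode channel aggregate) on the
        same trials as the session's trial table.
    target_n_backs
        Images at other n-backs (and scheduling fillers) are discarded.
    require_choice
        Drop images lacking a behavioral report on both rows — the rule
        for behaving sessions; synthetic sessions without simulated
        behavior can keep all images.
    group_by
        "n_back" (memory task) or "category" (categorical task variant).

    Per group, the pseudoimage count is the minimum across sessions;
    richer sessions are thinned with :func:`memorability_subsample`,
    images are paired across sessions by memorability rank (ties broken by
    image id), and pseudoimage memorability is the mean over contributors.
    """
    if not sessions:
        raise ValueError("need at least one session")
    if len(band_responses) != len(sessions):
        raise ValueError("one band-response array per session required")
    if group_by not in ("n_back", "category"):
        raise ValueError("group_by must be 'n_back' or 'category'")
    targets = set(int(n) for n in target_n_backs)

    tables = []
    for s in sessions:
        imgs = _image_table(s)
        imgs = imgs[imgs["n_back"].isin(targets) & ~imgs["is_filler"]]
        if require_choice:
            imgs = imgs[imgs["reported"]]
        tables.append(imgs)

    all_groups = [set(t[group_by].dropna().unique()) for t in tables]
    groups = sorted(set.intersection(*all_groups), key=str)
    dropped = set.union(*all_groups) - set(groups)
    if dropped:
        log.info("groups dropped (absent from some session): %s",
                 sorted(dropped, key=str))
    if not groups:
        raise ValueError("no group present in every session at the target n-backs")

    # per session, the aligned image rows in pseudoimage order
    selected: list[list[pd.DataFrame]] = [[] for _ in sessions]
    meta_rows: list[dict] = []
    for g in groups:
        ranked_per_session = []
        for imgs in tables:
            sub = imgs[imgs[group_by] == g]
            # memorability rank order, ties broken by image id for determinism
            order = np.lexsort((sub.index.to_numpy(), sub["memorability"].to_numpy()))
            ranked_per_session.append(sub.iloc[order])
        k = min(len(r) for r in ranked_per_session)
        if k == 0:
            continue
        aligned = [
            r.loc[memorability_subsample(list(r.index), k)]
            for r in ranked_per_session
        ]
        for rank in range(k):
            contributors = [a.iloc[rank] for a in aligned]
            meta_rows.append(
                {
                    "n_back": int(contributors[0]["n_back"])
                    if group_by == "n_back"
                    else int(round(np.mean([c["n_back"] for c in contributors]))),
                    "memorability": float(
                        np.mean([c["memorability"] for c in contributors])
                    ),
                    "category": (
                        g if group_by == "category" else contributors[0]["category"]
                    ),
                }
            )
        for s_i, a in enumerate(aligned):
            selected[s_i].append(a)

    if not meta_rows:
        raise ValueError("no pseudoimages could be aligned at the target n-backs")
    images = pd.DataFrame(meta_rows)

    spk_nov, spk_rep, ch_nov, ch_rep, obs_rows = [], [], [], [], []
    for session, band, parts in zip(sessions, band_responses, selected):
        sel = pd.concat(parts)
        nov_cols = sel["novel_col"].to_numpy(dtype=int)
        rep_cols = sel["repeated_col"].to_numpy(dtype=int)
        spk_nov.append(session.spike_counts[:, nov_cols].astype(float))
        spk_rep.append(session.spike_counts[:, rep_cols].astype(float))
        band = np.asarray(band, dtype=float)
        if band.shape[1] != len(session.trial_table):
            raise ValueError("band response trial count mismatch")
        per_unit = band[session.unit_to_channel]  # channel row repeated per unit
        ch_nov.append(per_unit[:, nov_cols])
        ch_rep.append(per_unit[:, rep_cols])
        for u in range(session.n_units):
            obs_rows.append(
                {
                    "session": session.session_id,
                    "unit": u,
                    "channel": int(session.unit_to_channel[u]),
                }
            )

    return Pseudopopulation(
        images=images.reset_index(drop=True),
        spikes_novel=np.vstack(spk_nov),
        spikes_repeated=np.vstack(spk_rep),
        channels_novel=np.vstack(ch_nov),
        channels_repeated=np.vstack(ch_rep),
        observations=pd.DataFrame(obs_rows),
        analysis_window_ms=analysis_window_ms,
    )
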