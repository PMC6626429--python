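"""Positional label propagation along scaffolds.

Fragments cut from the same scaffold usually descend from the same
progenitor, so an unclassified fragment can inherit the label of its
neighbours: each ambiguous fragment receives the bp-weighted majority label
of up to ``window`` labeled fragments on each side within its scaffold,
provided the vote margin is met.  Sweeps repeat until a fixed point; newly
labeled fragments vote in later sweeps, and already-labeled fragments are
never changed.  Conversely, scaffolds whose fragments carry mixed labels are
flagged: on validated assemblies these are candidate translocations, on
draft assemblies candidate mis-assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import AMBIGUOUS, BinningState
from .fragmentation import FragmentSet


def propagate(bins: BinningState, fragments: FragmentSet, window: int = 2,
              min_margin: int = 1) -> tuple[BinningState, np.ndarray]:
    """Fill ambiguous fragments from their scaffold neighbours.

    ``window`` labeled fragments are consulted per side; votes are weighted
    by voter length in bp and an assignment requires
    ``votes_best - votes_second >= min_margin`` (margin in bp; the default 1
    demands any strict majority).  Returns the new state and a boolean mask
    of fragments labeled by propagation.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    labels = bins.labels.copy()
    lengths = bins.fragment_lengths
    newly = np.zeros(labels.size, dtype=bool)
    order = fragments.by_scaffold()
    changed = True
    while changed:
        changed = False
        for idxs in order.values():
            for pos, i in enumerate(idxs):
                if labels[i] != AMBIGUOUS:
                    continue
                votes = np.zeros(bins.n_bins, dtype=np.int64)
                found = 0
                for j in range(pos - 1, -1, -1):  # up to `window` labeled on the left
                    lab = labels[idxs[j]]
                    if lab != AMBIGUOUS:
                        votes[lab] += lengths[idxs[j]]
                        found += 1
                        if found >= window:
                            break
                found = 0
                for j in range(pos + 1, len(idxs)):
                    lab = labels[idxs[j]]
                    if lab != AMBIGUOUS:
                        votes[lab] += lengths[idxs[j]]
                        found += 1
                        if found >= window:
                            break
                if votes.sum() == 0:
                    continue
                ranked = np.sort(votes)
                if ranked[-1] - (ranked[-2] if votes.size > 1 else 0) >= min_margin:
                    labels[i] = int(np.argmax(votes))
                    newly[i] = True
                    changed = True
    out = bins.with_labels(labels)
    out.history.append(out.bin_bp)
    return out, newly


@dataclass
class DiscordantScaffold:
    scaffold_id: str
    runs: list[tuple[str, int]]  # (label name, run length in fragments)


def flag_discordant(bins: BinningState, fragments: FragmentSet) -> list[DiscordantScaffold]:
    """Scaffolds whose labeled fragments span >= 2 bins, with run summaries.

    Mixed-label scaffolds indicate either real inter-subgenome translocations
    or assembly errors; the runs-of-labels summary supports that review.
    """
    names = bins.label_names
    out: list[DiscordantScaffold] = []
    for scaffold, idxs in fragments.by_scaffold().items():
        labs = [int(bins.labels[i]) for i in idxs if bins.labels[i] != AMBIGUOUS]
        if len(set(labs)) < 2:
            continue
        runs: list[tuple[str, int]] = []
        for lab in labs:
            name = names[lab]
            if runs and runs[-1][0] == name:
                runs[-1] = (name, runs[-1][1] + 1)
            else:
                runs.append((name, 1))
        out.append(DiscordantScaffold(scaffold, runs))
    return out
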