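"""Matched background intron set.

For each retained intron, one intron is drawn at random from genes with no
retention evidence such that it has a similar length and GC content (within
5%) and an identical internal pA-tract length.  The background set is used
for covariate-controlled comparisons (e.g. pA-tract statistics) without
confounding by intron size or base composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from cirtseq.annotation import IntronRecord

GC_WINDOW = 0.05  # |GC difference| <= 5 percentage points
LENGTH_WINDOW = 0.05  # background length within +/-5% of the retained length


@dataclass
class MatchedPair:
    retained: IntronRecord
    background: IntronRecord

    @property
    def length_ratio(self) -> float:
        return self.background.length / self.retained.length

    @property
    def gc_delta(self) -> float:
        return abs(self.background.gc_fraction - self.retained.gc_fraction)


def _matches(
    retained: IntronRecord,
    cand: IntronRecord,
    gc_window: float,
    length_window: float,
) -> bool:
    if cand.max_internal_pa_tract != retained.max_internal_pa_tract:
        return False
    if math.isnan(cand.gc_fraction) or math.isnan(retained.gc_fraction):
        return False
    if abs(cand.gc_fraction - retained.gc_fraction) > gc_window:
        return False
    lo = retained.length * (1 - length_window)
    hi = retained.length * (1 + length_window)
    return lo <= cand.length <= hi


def sample_matched_background(
    retained_introns: Sequence[IntronRecord],
    candidate_pool: Sequence[IntronRecord],
    seed: int,
    gc_window: float = GC_WINDOW,
    length_window: float = LENGTH_WINDOW,
) -> tuple[list[MatchedPair], list[IntronRecord]]:
    """Sample one matched background intron per retained intron.

    ``candidate_pool`` must already exclude every gene with a passed
    retention call.  Matching requires |GC delta| <= ``gc_window`` (in
    fraction units), length within ``length_window`` relative, and an
    identical maximal internal pA-tract length (0 meaning no tract at the
    reporting threshold).  Sampling is uniform, seeded, and without
    replacement; retained introns with an empty candidate set are returned
    as unmatched, never silently dropped.
    """
    rng = np.random.default_rng(seed)
    available = list(candidate_pool)
    pairs: list[MatchedPair] = []
    unmatched: list[IntronRecord] = []
    for ret in retained_introns:
        idxs = [
            i
            for i, cand in enumerate(available)
            if _matches(ret, cand, gc_window, length_window)
        ]
        if not idxs:
            unmatched.append(ret)
            continue
        pick = idxs[int(rng.integers(len(idxs)))]
        pairs.append(MatchedPair(retained=ret, background=available[pick]))
        available.pop(pick)
    return pairs, unmatched


def write_pairs_tsv(pairs: Sequence[MatchedPair], path) -> None:
    with open(path, "w") as out:
        out.write(
            "retained\tretained_len\tretained_gc\tretained_pa\t"
            "background\tbackground_len\tbackground_gc\tbackground_pa\n"
        )
        for p in pairs:
            r, b = p.retained, p.background
            out.write(
                f"{r.name}\t{r.length}\t{r.gc_fraction:.4f}\t{r.max_internal_pa_tract}\t"
                f"{b.name}\t{b.length}\t{b.gc_fraction:.4f}\t{b.max_internal_pa_tract}\n"
            )
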