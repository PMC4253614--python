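"""Chromatin state at breakpoints.

Two analyses over a ChromHMM-style segmentation (a tiling of each chromosome
into labeled state blocks):

* a per-state histogram of the states observed at all breakpoint ends,
  compared with the genome composition of the segmentation (expected
  fraction = state's covered bases / total covered bases), with binomial
  standard errors sqrt(p(1-p)/n);
* an event-level unordered state-pair matrix, compared against an
  independence null built from the included events' own end-state marginals
  (expected{a,b} = 2·m_a·m_b for a ≠ b and m_a² on the diagonal) — i.e. the
  expectation if the two ends of an event were paired at random.

Breakpoints falling in segmentation gaps are excluded with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome import GenomeLayout
from .io import SMCallset

__all__ = [
    "StateSegmentation",
    "StateHistogram",
    "StatePairMatrix",
    "state_histogram",
    "pair_matrix",
    "state_group_summary",
    "default_state_groups",
]

logger = logging.getLogger(__name__)


@dataclass
class StateSegmentation:
    """Per-chromosome sorted non-overlapping labeled blocks plus a catalog."""

    layout: GenomeLayout
    catalog: list[str]
    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    codes: dict[str, np.ndarray]  # indices into catalog
    cell_line: str = ""
    lab: str = ""

    def state_at(self, chrom: str, pos: int) -> str | None:
        """Label of the block covering ``pos``; None in a gap."""
        s = self.starts.get(chrom)
        if s is None or len(s) == 0:
            return None
        i = int(np.searchsorted(s, pos, side="right")) - 1
        if i < 0 or pos >= self.ends[chrom][i]:
            return None
        return self.catalog[self.codes[chrom][i]]

    def state_sizes(self) -> np.ndarray:
        """Covered base pairs per catalog state."""
        sizes = np.zeros(len(self.catalog), dtype=np.int64)
        for chrom in self.starts:
            np.add.at(
                sizes, self.codes[chrom], self.ends[chrom] - self.starts[chrom]
            )
        return sizes


@dataclass
class StateHistogram:
    catalog: list[str]
    observed_counts: np.ndarray
    n: int
    n_uncovered: int
    expected_freq: np.ndarray

    @property
    def observed_freq(self) -> np.ndarray:
        return self.observed_counts / self.n

    @property
    def se(self) -> np.ndarray:
        p = self.observed_freq
        return np.sqrt(p * (1.0 - p) / self.n)


@dataclass
class StatePairMatrix:
    """Unordered breakpoint-pair state co-occurrence vs independence null."""

    catalog: list[str]
    observed_counts: np.ndarray  # upper-triangular (incl. diagonal) counts
    n_events: int
    marginals: np.ndarray  # end-state frequencies of the included events

    def _triu_mask(self) -> np.ndarray:
        k = len(self.catalog)
        return np.triu(np.ones((k, k), dtype=bool))

    @property
    def observed_freq(self) -> np.ndarray:
        return self.observed_counts / self.n_events

    @property
    def expected_freq(self) -> np.ndarray:
        m = self.marginals
        exp = 2.0 * np.outer(m, m)
        np.fill_diagonal(exp, m**2)
        return np.where(self._triu_mask(), exp, 0.0)

    @property
    def difference(self) -> np.ndarray:
        return self.observed_freq - self.expected_freq


def _score_ends(callset: SMCallset, seg: StateSegmentation):
    """State codes for each event's two ends; None entries mark gaps."""
    code_of = {s: i for i, s in enumerate(seg.catalog)}
    scored = []
    for ev in callset.events:
        a = seg.state_at(ev.chrom1, ev.pos1)
        b = seg.state_at(ev.chrom2, ev.pos2)
        scored.append(
            (
                code_of[a] if a is not None else None,
                code_of[b] if b is not None else None,
            )
        )
    return scored


def state_histogram(
    callset: SMCallset, seg: StateSegmentation, layout: GenomeLayout | None = None
) -> StateHistogram:
    """Observed state frequencies over all scored breakpoint ends."""
    counts = np.zeros(len(seg.catalog), dtype=np.int64)
    uncovered = 0
    for a, b in _score_ends(callset, seg):
        for code in (a, b):
            if code is None:
                uncovered += 1
            else:
                counts[code] += 1
    n = int(counts.sum())
    if n == 0:
        raise ValueError("no breakpoint falls inside the segmentation")
    if uncovered:
        logger.info("%d breakpoint ends in segmentation gaps excluded", uncovered)
    sizes = seg.state_sizes()
    return StateHistogram(
        catalog=list(seg.catalog),
        observed_counts=counts,
        n=n,
        n_uncovered=uncovered,
        expected_freq=sizes / sizes.sum(),
    )


def pair_matrix(
    callset: SMCallset,
    seg: StateSegmentation,
    interchromosomal_only: bool = False,
) -> StatePairMatrix:
    """Unordered end-state pair frequencies of events with both ends scored."""
    events = callset.subset("inter") if interchromosomal_only else callset
    k = len(seg.catalog)
    counts = np.zeros((k, k), dtype=np.int64)
    marg = np.zeros(k, dtype=np.int64)
    n = 0
    for a, b in _score_ends(events, seg):
        if a is None or b is None:
            continue
        lo, hi = min(a, b), max(a, b)
        counts[lo, hi] += 1
        marg[a] += 1
        marg[b] += 1
        n += 1
    if n == 0:
        raise ValueError("no event has both breakpoints inside the segmentation")
    return StatePairMatrix(
        catalog=list(seg.catalog),
        observed_counts=counts,
        n_events=n,
        marginals=marg / (2 * n),
    )


def default_state_groups(catalog: list[str]) -> dict[str, list[str]]:
    """Functional groupings by the numeric prefix of 15-state labels.

    Promoters are states 1-3, enhancers 4-7, transcription 9-11 and
    heterochromatin state 13; only states present in the catalog are used.
    """
    wanted = {
        "promoter": {1, 2, 3},
        "enhancer": {4, 5, 6, 7},
        "transcription": {9, 10, 11},
        "heterochromatin": {13},
    }
    groups: dict[str, list[str]] = {}
    for name, nums in wanted.items():
        members = []
        for label in catalog:
            prefix = label.split("_", 1)[0]
            if prefix.isdigit() and int(prefix) in nums:
                members.append(label)
        if members:
            groups[name] = members
    return groups


@dataclass
class GroupSummary:
    group: str
    observed_freq: float
    expected_freq: float
    se: float


def state_group_summary(
    hist: StateHistogram, groups: dict[str, list[str]]
) -> list[GroupSummary]:
    """Summed observed/expected frequencies per named state group."""
    index = {s: i for i, s in enumerate(hist.catalog)}
    out = []
    for name, members in groups.items():
        unknown = [m for m in members if m not in index]
        if unknown:
            raise ValueError(f"group {name!r} references unknown states {unknown}")
        idx = [index[m] for m in members]
        p = float(hist.observed_freq[idx].sum())
        out.append(
            GroupSummary(
                group=name,
                observed_freq=p,
                expected_freq=float(hist.expected_freq[idx].sum()),
                se=float(np.sqrt(p * (1.0 - p) / hist.n)),
            )
        )
    return out
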