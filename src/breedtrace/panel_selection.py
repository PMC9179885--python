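"""Reduced-panel construction by delta ranking.

A *selection scheme* assigns each pairwise breed comparison a number
of slots; each pair contributes its highest-delta markers not already
selected (a marker can fill only one slot — later pairs take their
next-ranked marker instead).  The default schemes reproduce the study
design: a 9-SNP focal-breed core (3 + 3 + 2 + 1 over the focal breed's
four comparisons), 3 further markers targeted at the near-clustering
pair flagged by MDS (the 12-SNP core), and an 8-SNP augmentation over
the remaining between-breed pairs (the 20-SNP final panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .popgen_stats import AlleleFrequencyTable, delta_table


class InsufficientSNPsError(ValueError):
    """A pair's slots cannot be filled with distinct defined-delta SNPs."""


@dataclass(frozen=True)
class PairSlot:
    pair: tuple[str, str]
    count: int

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise ValueError(f"pair must name two distinct populations: {self.pair}")
        if self.count < 1:
            raise ValueError(f"slot count must be >= 1, got {self.count} for {self.pair}")


@dataclass(frozen=True)
class SelectionScheme:
    """Ordered (pair, count) slots; processed in the given order."""

    slots: tuple[PairSlot, ...]

    @classmethod
    def of(cls, *items: tuple[tuple[str, str], int]) -> "SelectionScheme":
        return cls(tuple(PairSlot(tuple(pair), count) for pair, count in items))

    @property
    def total(self) -> int:
        return sum(s.count for s in self.slots)

    def pairs(self) -> list[tuple[str, str]]:
        return [s.pair for s in self.slots]


@dataclass(frozen=True)
class PanelEntry:
    snp_id: str
    source_pair: tuple[str, str]
    delta: float
    stage: str  # core | mds_guided | augmentation


@dataclass
class SNPPanel:
    """Ordered selected markers with full selection provenance."""

    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.snp_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("panel contains duplicate snp_ids")

    @property
    def snp_ids(self) -> list[str]:
        return [e.snp_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in set(self.snp_ids)

    def to_frame(self, aft: AlleleFrequencyTable | None = None) -> pd.DataFrame:
        rows = []
        meta = {}
        if aft is not None and aft.snps is not None:
            meta = {s.snp_id: s for s in aft.snps}
        for e in self.entries:
            m = meta.get(e.snp_id)
            rows.append(
                {
                    "snp_id": e.snp_id,
                    "rs_id": m.rs_id if m else None,
                    "chromosome": m.chromosome if m else None,
                    "position": m.position if m else None,
                    "pair": f"{e.source_pair[0]}-{e.source_pair[1]}",
                    "delta": e.delta,
                    "stage": e.stage,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["snp_id", "rs_id", "chromosome", "position", "pair", "delta", "stage"],
        )

    def to_tsv(self, path: str | Path, aft: AlleleFrequencyTable | None = None) -> None:
        self.to_frame(aft).to_csv(path, sep="\t", index=False)


def _fill_slot(
    aft: AlleleFrequencyTable,
    pair: tuple[str, str],
    count: int,
    taken: set[str],
    stage: str,
) -> list[PanelEntry]:
    table = delta_table(aft, *pair)
    picked: list[PanelEntry] = []
    for row in table.itertuples(index=False):
        if len(picked) == count:
            break
        if row.snp_id in taken:
            continue
        picked.append(PanelEntry(row.snp_id, tuple(pair), float(row.delta), stage))
        taken.add(row.snp_id)
    if len(picked) < count:
        raise InsufficientSNPsError(
            f"pair {pair[0]}-{pair[1]}: only {len(picked)} distinct SNPs with "
            f"defined delta available for {count} slots"
        )
    return picked


def select_panel(
    aft: AlleleFrequencyTable,
    scheme: SelectionScheme,
    stage: str = "core",
    exclude: Iterable[str] = (),
) -> SNPPanel:
    """Fill the scheme's slots pair by pair with top-delta markers.

    Pairs are processed in scheme order; an already-selected marker is
    skipped and the pair's next-ranked marker fills the slot, so the
    panel size always equals the scheme total.
    """
    taken = set(exclude)
    entries: list[PanelEntry] = []
    for slot in scheme.slots:
        entries += _fill_slot(aft, slot.pair, slot.count, taken, stage)
    return SNPPanel(entries)


def mds_guided_slots(
    aft: AlleleFrequencyTable,
    pair_list: Sequence[tuple[str, str]],
    count: int,
    exclude: Iterable[str] = (),
) -> list[PanelEntry]:
    """Extra markers targeted at near-clustering breed pairs.

    Operationalized as delta ranking pooled over ``pair_list``: all
    (marker, pair) deltas are ranked together and the top ``count``
    distinct markers not in ``exclude`` are returned (stage
    ``mds_guided``).  ``count`` 0 returns an empty list.
    """
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    if count == 0:
        return []
    rows = []
    for pair in pair_list:
        t = delta_table(aft, *pair)
        t["pair_i"], t["pair_j"] = pair
        rows.append(t)
    pooled = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["delta", "snp_id"], ascending=[False, True], kind="mergesort")
    )
    taken = set(exclude)
    picked: list[PanelEntry] = []
    for row in pooled.itertuples(index=False):
        if len(picked) == count:
            break
        if row.snp_id in taken:
            continue
        picked.append(
            PanelEntry(row.snp_id, (row.pair_i, row.pair_j), float(row.delta), "mds_guided")
        )
        taken.add(row.snp_id)
    if len(picked) < count:
        raise InsufficientSNPsError(
            f"pairs {pair_list}: only {len(picked)} distinct SNPs available "
            f"for {count} MDS-guided slots"
        )
    return picked


def augment_panel(
    panel: SNPPanel, aft: AlleleFrequencyTable, extra: SelectionScheme
) -> SNPPanel:
    """Append top-delta markers for the non-focal breed pairs.

    Markers already in ``panel`` are skipped (their pair takes its
    next-ranked marker), so the result grows by exactly the scheme
    total.  Returns a new panel; the input is left untouched.
    """
    added = select_panel(
        aft, extra, stage="augmentation", exclude=panel.snp_ids
    )
    return SNPPanel(panel.entries + added.entries)


def build_core_panel(
    aft: AlleleFrequencyTable,
    core: SelectionScheme,
    mds_pairs: Sequence[tuple[str, str]] = (),
    mds_count: int = 0,
) -> SNPPanel:
    """Core scheme plus MDS-guided additions in one call."""
    panel = select_panel(aft, core, stage="core")
    extra = mds_guided_slots(aft, mds_pairs, mds_count, exclude=panel.snp_ids)
    return SNPPanel(panel.entries + extra)


# -- study-design default schemes -------------------------------------------

def focal_core_scheme(
    focal: str = "NS",
    others: Sequence[str] = ("LR", "LW", "WB", "DU"),
    counts: Sequence[int] = (3, 3, 2, 1),
) -> SelectionScheme:
    """3+3+2+1 slots for the focal breed's four pairwise comparisons."""
    return SelectionScheme.of(
        *(((focal, other), c) for other, c in zip(others, counts))
    )


def default_augmentation_scheme(
    pairs_counts: Sequence[tuple[tuple[str, str], int]] = (
        (("LR", "LW"), 3),
        (("LR", "WB"), 1),
        (("LW", "WB"), 1),
        (("DU", "WB"), 1),
        (("LR", "DU"), 1),
        (("LW", "DU"), 1),
    ),
) -> SelectionScheme:
    """8 between-breed slots weighted toward the hardest pair (LR-LW)."""
    return SelectionScheme.of(*pairs_counts)
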