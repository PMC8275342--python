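"""Editing-outcome statistics from per-target repair-event records.

Each sequenced read at an edited target is reduced to its *net* indel length
(inserted bases minus deleted bases, parsed from a CIGAR string when counts
come from alignments).  From the indel-bearing reads of one target, six
statistics are computed, all as fractions of indel outcomes I+D:

* ``ins1``     — 1 bp insertion probability, I1bp / (I+D)
* ``del1``     — 1 bp deletion probability,  D1bp / (I+D)
* ``del_freq`` — deletion frequency,         D / (I+D)
* ``fs1``      — frameshift of 1 (|net| mod 3 == 1) frequency
* ``fs2``      — frameshift of 2 (|net| mod 3 == 2) frequency
* ``fs_total`` — fs1 + fs2

Reads whose net length change is zero (including reads with balanced internal
insertions and deletions) count as non-indel outcomes and enter neither
numerator nor denominator.  A read carrying several indel operations
contributes one outcome, classified by its net length — the net is what
determines the reading frame.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import CigarError, InputError, UndefinedProfileError

logger = logging.getLogger(__name__)

TASK_NAMES = ("ins1", "del1", "del_freq", "fs1", "fs2", "fs_total")

_CIGAR_TOKEN = re.compile(r"(\d+)([A-Za-z=])")
_SUPPORTED_OPS = set("MIDS=X")


@dataclass(frozen=True)
class RepairEvent:
    """One repair outcome class at a target: net indel length and read count."""

    net_indel_length: int
    count: int
    cigar: str | None = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise InputError(f"negative read count {self.count}")


def parse_cigar(cigar: str, count: int = 1) -> RepairEvent:
    """Parse a CIGAR string into a repair event.

    Net indel length is the sum of I-operation lengths minus the sum of
    D-operation lengths.  Ops outside {M, I, D, S, =, X} are rejected.
    """
    if not cigar:
        raise CigarError("empty CIGAR string")
    consumed = 0
    net = 0
    for m in _CIGAR_TOKEN.finditer(cigar):
        length, op = int(m.group(1)), m.group(2)
        if op not in _SUPPORTED_OPS:
            raise CigarError(f"unsupported CIGAR op {op!r} in {cigar!r}")
        if op == "I":
            net += length
        elif op == "D":
            net -= length
        consumed += len(m.group(0))
    if consumed != len(cigar):
        raise CigarError(f"malformed CIGAR string {cigar!r}")
    return RepairEvent(net_indel_length=net, count=count, cigar=cigar)


@dataclass(frozen=True)
class OutcomeProfile:
    """The six editing-outcome statistics, each in [0, 1]."""

    ins1: float
    del1: float
    del_freq: float
    fs1: float
    fs2: float
    fs_total: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
            raise InputError(f"profile outside [0,1]: {arr}")
        if abs(self.fs_total - (self.fs1 + self.fs2)) > 1e-9:
            raise InputError("fs_total != fs1 + fs2")
        if self.ins1 > 1 - self.del_freq + 1e-9 or self.del1 > self.del_freq + 1e-9:
            raise InputError("insertion/deletion statistics inconsistent")

    def as_array(self) -> np.ndarray:
        return np.array([self.ins1, self.del1, self.del_freq,
                         self.fs1, self.fs2, self.fs_total])

    @classmethod
    def from_array(cls, arr) -> "OutcomeProfile":
        return cls(*(float(v) for v in np.asarray(arr)))


def compute_profile(events: Iterable[RepairEvent]) -> OutcomeProfile:
    """Six outcome statistics over the indel-bearing reads of one target.

    Order-invariant and merge-invariant: only the multiset of
    (net length, count) pairs matters.
    """
    ins = dels = ins1 = del1 = fs1 = fs2 = 0
    for ev in events:
        net, c = ev.net_indel_length, ev.count
        if c == 0 or net == 0:
            continue
        if net > 0:
            ins += c
            if net == 1:
                ins1 += c
        else:
            dels += c
            if net == -1:
                del1 += c
        m = abs(net) % 3
        if m == 1:
            fs1 += c
        elif m == 2:
            fs2 += c
    total = ins + dels
    if total == 0:
        raise UndefinedProfileError("no indel-bearing reads; profile undefined")
    fs1_f, fs2_f = fs1 / total, fs2 / total
    return OutcomeProfile(ins1=ins1 / total, del1=del1 / total,
                          del_freq=dels / total, fs1=fs1_f, fs2=fs2_f,
                          fs_total=fs1_f + fs2_f)  # exact identity


def profile_table(per_target_events: Sequence[tuple[str, Sequence[RepairEvent]]],
                  min_indel_reads: int = 1) -> pd.DataFrame:
    """Profiles for every target with enough indel read support.

    Targets whose indel-bearing read count falls below ``min_indel_reads``
    (or is zero) are dropped with a log entry.  Duplicate site ids are an
    input error rather than silently merged.
    """
    seen: set[str] = set()
    rows = []
    for site_id, events in per_target_events:
        if site_id in seen:
            raise InputError(f"duplicate site_id group {site_id!r}")
        seen.add(site_id)
        support = sum(ev.count for ev in events
                      if ev.net_indel_length != 0 and ev.count > 0)
        if support < max(min_indel_reads, 1):
            logger.info("dropping %s: %d indel reads < threshold %d",
                        site_id, support, min_indel_reads)
            continue
        prof = compute_profile(events)
        rows.append((site_id, *prof.as_array()))
    return pd.DataFrame(rows, columns=["site_id", *TASK_NAMES])


# -- I/O ----------------------------------------------------------------------

def read_events_tsv(path) -> list[tuple[str, list[RepairEvent]]]:
    """Read (site_id, cigar-or-net, count) rows grouped by site.

    The second column is either a CIGAR string or a signed integer net indel
    length; the file must carry columns ``site_id``, ``count`` and one of
    ``cigar`` / ``net_indel_length``.
    """
    df = pd.read_csv(path, sep="\t")
    has_cigar = "cigar" in df.columns
    groups: list[tuple[str, list[RepairEvent]]] = []
    for site_id, sub in df.groupby("site_id", sort=False):
        events = []
        for i in sub.index:
            count = int(sub.at[i, "count"])
            cig = sub.at[i, "cigar"] if has_cigar else None
            if isinstance(cig, str) and cig:
                events.append(parse_cigar(cig, count=count))
            else:
                events.append(RepairEvent(int(sub.at[i, "net_indel_length"]), count))
        groups.append((str(site_id), events))
    return groups


def write_profiles_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
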