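"""Read processing: probe matching, UMI deduplication, FASTQ counting.

Each read is expected to start with a 7-nt UMI followed immediately by the
ligated probe insert (adapters are assumed trimmed by the sequencer).  A
read is assigned to the probe pair whose left half-probe best matches at the
insert position and whose right half-probe best matches immediately after,
each within a Hamming-distance tolerance (default 2 mismatches per half, no
indels).  Reads whose two halves best-match different probe pairs are
chimeric ligation artefacts; ambiguous or poorly matching reads are
discarded.  Molecule counts are the number of distinct UMIs per
(sample, marker), which collapses PCR duplicates; an optional directional
Hamming-1 collapse additionally absorbs single sequencing errors in the UMI
itself.

A sample is reportable ("interpretable") only when at least 5000
deduplicated molecules are detected across all markers.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from .panel import DNA_ALPHABET, PanelDefinition, ligation_products

#: minimum deduplicated molecules for a sample to be reportable
MIN_INTERPRETABLE_UMIS = 5000

NO_MATCH = "NO_MATCH"
CHIMERA = "CHIMERA"

@dataclass(frozen=True)
class ReadLayout:
    """Positions of the UMI and the ligated insert within a read."""

    umi_offset: int = 0
    umi_length: int = 7
    insert_offset: int = 7
    max_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.umi_offset < 0 or self.insert_offset < 0:
            raise ValueError("offsets must be non-negative")
        umi_end = self.umi_offset + self.umi_length
        if self.umi_offset < self.insert_offset < umi_end:
            raise ValueError("UMI and insert intervals overlap")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class ProbeMatcher:
    """Vectorised Hamming matcher over a panel's half-probes.

    Probes are grouped by half-probe length so each read segment is compared
    against a (n_probes x length) byte matrix in one numpy operation.
    """

    def __init__(self, panel: PanelDefinition, layout: ReadLayout) -> None:
        if layout.umi_length != panel.umi_length:
            raise ValueError(
                f"layout umi_length {layout.umi_length} != panel umi_length "
                f"{panel.umi_length}")
        self.panel = panel
        self.layout = layout
        ligation_products(panel)  # validates injectivity
        self.marker_ids = panel.marker_ids
        self._left_groups: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._right_groups: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        by_llen: dict[int, list[int]] = defaultdict(list)
        by_off: dict[tuple[int, int], list[int]] = defaultdict(list)
        for i, p in enumerate(panel.probes):
            by_llen[len(p.left_seq)].append(i)
            # right half starts where this probe's left half ends
            by_off[(len(p.left_seq), len(p.right_seq))].append(i)
        for llen, idx in by_llen.items():
            mat = np.stack([_encode(panel.probes[i].left_seq) for i in idx])
            self._left_groups[llen] = (np.asarray(idx), mat)
        for (llen, rlen), idx in by_off.items():
            mat = np.stack([_encode(panel.probes[i].right_seq) for i in idx])
            self._right_groups[(llen, rlen)] = (np.asarray(idx), mat)
        self.min_read_length = layout.insert_offset + min(
            len(p.product) for p in panel.probes)

    def _best(self, read_b: np.ndarray, groups, start_of) -> tuple[int, int, bool]:
        """(probe index, distance, unique) of the best-matching half."""
        best_i, best_d, unique = -1, 10 ** 9, True
        for key, (idx, mat) in groups.items():
            start, length = start_of(key, mat.shape[1])
            seg = read_b[start:start + length]
            if seg.size < length:
                continue
            d = (mat != seg).sum(axis=1)
            j = int(np.argmin(d))
            dj = int(d[j])
            if dj < best_d:
                best_i, best_d = int(idx[j]), dj
                unique = int((d == dj).sum()) == 1
            elif dj == best_d:
                unique = False
        return best_i, best_d, unique

    def match(self, read: str) -> tuple[str, str]:
        """Assign one read: returns (marker_id | NO_MATCH | CHIMERA, umi)."""
        lay = self.layout
        read = read.upper()
        umi = read[lay.umi_offset:lay.umi_offset + lay.umi_length]
        read_b = _encode(read)
        li, ld, lu = self._best(
            read_b, self._left_groups,
            lambda llen, n: (lay.insert_offset, n))
        ri, rd, ru = self._best(
            read_b, self._right_groups,
            lambda key, n: (lay.insert_offset + key[0], n))
        if li < 0 or ri < 0:
            return NO_MATCH, umi
        if ld > lay.max_mismatches or rd > lay.max_mismatches:
            return NO_MATCH, umi
        if not (lu and ru):
            # ambiguous best match must not inflate counts
            return NO_MATCH, umi
        if li != ri:
            return CHIMERA, umi
        return self.marker_ids[li], umi


def match_read(read: str, panel: PanelDefinition,
               layout: ReadLayout | None = None) -> tuple[str, str]:
    """Convenience single-read wrapper around :class:`ProbeMatcher`."""
    layout = layout or ReadLayout(umi_length=panel.umi_length,
                                  insert_offset=panel.umi_length)
    return ProbeMatcher(panel, layout).match(read)


@dataclass
class UmiCountMatrix:
    """Samples x markers matrix of deduplicated molecule counts + QC."""

    counts: pd.DataFrame          # int, rows = samples, cols = marker_ids
    discard_stats: pd.DataFrame   # assigned / no_match / chimeric / below_quality

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def markers(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_umis(self) -> pd.Series:
        return self.counts.sum(axis=1).rename("total_umis")

    @property
    def interpretable(self) -> pd.Series:
        return (self.total_umis >= MIN_INTERPRETABLE_UMIS).rename("interpretable")

    @property
    def qc(self) -> pd.DataFrame:
        qc = pd.concat([self.total_umis, self.interpretable,
                        self.discard_stats], axis=1)
        qc.index.name = "sample_id"
        return qc

    def write(self, counts_path: str | Path,
              qc_path: str | Path | None = None) -> None:
        out = self.counts.copy()
        out.index.name = "sample_id"
        out.to_csv(counts_path, sep="\t")
        if qc_path is not None:
            self.qc.to_csv(qc_path, sep="\t")

    @classmethod
    def read(cls, counts_path: str | Path,
             qc_path: str | Path | None = None) -> "UmiCountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="sample_id")
        if qc_path is not None:
            qc = pd.read_csv(qc_path, sep="\t", index_col="sample_id")
            cols = [c for c in ("assigned", "no_match", "chimeric",
                                "below_quality") if c in qc.columns]
            stats = qc[cols]
        else:
            stats = pd.DataFrame(0, index=counts.index,
                                 columns=["assigned", "no_match", "chimeric",
                                          "below_quality"])
        return cls(counts=counts.astype(int), discard_stats=stats)


def _directional_collapse(umi_counts: Counter) -> int:
    """Number of molecules after directional Hamming-1 UMI collapse.

    A UMI is absorbed into a neighbour at Hamming distance 1 whose read
    count is at least ``2 * count - 1`` (the directional network rule),
    processing UMIs from most to least abundant.
    """
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    absorbed: set[str] = set()
    kept: list[str] = []
    for u in order:
        if u in absorbed:
            continue
        kept.append(u)
        stack = [u]
        while stack:
            parent = stack.pop()
            pc = umi_counts[parent]
            for pos in range(len(parent)):
                for base in "ACGT":
                    if base == parent[pos]:
                        continue
                    child = parent[:pos] + base + parent[pos + 1:]
                    if (child in umi_counts and child not in absorbed
                            and child not in kept
                            and pc >= 2 * umi_counts[child] - 1):
                        absorbed.add(child)
                        stack.append(child)
    return len(kept)


def collapse_umis(events: Iterable[tuple[str, str, str]],
                  markers: list[str] | None = None,
                  umi_collapse: str = "exact") -> UmiCountMatrix:
    """Deduplicate (sample, marker, umi) events into molecule counts.

    ``umi_collapse='exact'`` counts distinct UMI strings per (sample,
    marker); ``'hamming1'`` additionally merges UMIs within Hamming distance
    1 of a more abundant UMI (directional rule).  UMIs containing non-ACGT
    characters are dropped and counted as ``below_quality``.
    """
    if umi_collapse not in {"exact", "hamming1"}:
        raise ValueError(f"unknown umi_collapse {umi_collapse!r}")
    per_cell: dict[tuple[str, str], Counter] = defaultdict(Counter)
    below_quality: Counter = Counter()
    assigned: Counter = Counter()
    samples_seen: list[str] = []
    for sample, marker, umi in events:
        if sample not in samples_seen:
            samples_seen.append(sample)
        if set(umi) - DNA_ALPHABET:
            below_quality[sample] += 1
            continue
        assigned[sample] += 1
        per_cell[(sample, marker)][umi] += 1
    if markers is None:
        markers = sorted({m for _, m in per_cell})
    counts = pd.DataFrame(0, index=samples_seen, columns=markers, dtype=int)
    for (sample, marker), umis in per_cell.items():
        if marker not in counts.columns:
            continue
        if umi_collapse == "exact":
            n = len(umis)
        else:
            n = _directional_collapse(umis)
        counts.loc[sample, marker] = n
    stats = pd.DataFrame(0, index=samples_seen,
                         columns=["assigned", "no_match", "chimeric",
                                  "below_quality"])
    for sample, n in assigned.items():
        stats.loc[sample, "assigned"] = n
    for sample, n in below_quality.items():
        stats.loc[sample, "below_quality"] = n
    return UmiCountMatrix(counts=counts, discard_stats=stats)


class FastqFormatError(ValueError):
    """Raised on an unparseable FASTQ record, naming file and record index."""


def _peek_fastq(path: str | Path) -> None:
    import gzip
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        for line in fh:
            if line.strip():
                if not line.startswith("@"):
                    raise FastqFormatError(
                        f"{path}: record 0: expected '@' header, got "
                        f"{line[:20]!r}")
                return


def _iter_fastq(path: str | Path) -> Iterator[str]:
    _peek_fastq(path)
    try:
        with pysam.FastxFile(str(path)) as fh:
            for i, rec in enumerate(fh):
                if rec.sequence is None:
                    raise FastqFormatError(
                        f"{path}: record {i}: missing sequence")
                yield rec.sequence
    except FastqFormatError:
        raise
    except Exception as exc:  # pysam raises various parse errors
        raise FastqFormatError(f"{path}: malformed FASTQ ({exc})") from exc


def count_fastq(fastq_paths: dict[str, list[str | Path] | str | Path],
                panel: PanelDefinition,
                layout: ReadLayout | None = None,
                umi_collapse: str = "exact") -> UmiCountMatrix:
    """Count deduplicated molecules per sample and marker from FASTQ files.

    ``fastq_paths`` maps sample_id -> FASTQ path (or list of paths; ``.gz``
    accepted).  The result is invariant to read order and PCR duplication.
    """
    layout = layout or ReadLayout(umi_length=panel.umi_length,
                                  insert_offset=panel.umi_length)
    matcher = ProbeMatcher(panel, layout)
    per_cell: dict[tuple[str, str], Counter] = defaultdict(Counter)
    samples = list(fastq_paths)
    stats = pd.DataFrame(0, index=samples,
                         columns=["assigned", "no_match", "chimeric",
                                  "below_quality"])
    for sample, paths in fastq_paths.items():
        if isinstance(paths, (str, Path)):
            paths = [paths]
        for path in paths:
            for seq in _iter_fastq(path):
                if len(seq) < matcher.min_read_length:
                    stats.loc[sample, "below_quality"] += 1
                    continue
                marker, umi = matcher.match(seq)
                if marker == NO_MATCH:
                    stats.loc[sample, "no_match"] += 1
                elif marker == CHIMERA:
                    stats.loc[sample, "chimeric"] += 1
                elif set(umi) - DNA_ALPHABET:
                    stats.loc[sample, "below_quality"] += 1
                else:
                    stats.loc[sample, "assigned"] += 1
                    per_cell[(sample, marker)][umi] += 1
    counts = pd.DataFrame(0, index=samples, columns=panel.marker_ids,
                          dtype=int)
    for (sample, marker), umis in per_cell.items():
        if umi_collapse == "exact":
            counts.loc[sample, marker] = len(umis)
        elif umi_collapse == "hamming1":
            counts.loc[sample, marker] = _directional_collapse(umis)
        else:
            raise ValueError(f"unknown umi_collapse {umi_collapse!r}")
    return UmiCountMatrix(counts=counts, discard_stats=stats)
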