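"""Probe panel definition, loading, validation and ligation products.

The assay quantifies a targeted panel of marker transcripts with pairs of
half-probes that hybridise across an exon-exon junction on cDNA.  After
ligation and PCR, each sequencing read carries one ligated insert
(``left_seq + right_seq``) preceded by a 7-nt unique molecular identifier
(UMI).  The packaged default panel carries 137 distinct expression markers;
four genes (AICDA, BCL6, MYC, BCL2) are covered by two independent probe
pairs, and six mutation/virus-status loci are represented as
variant/reference probe pairs in the ``MUTATION`` group, which are excluded
from the expression-marker count.

The real probe sequences are proprietary; the packaged panel uses synthetic
placeholder half-probes whose ligation products are mutually separated by
edit distance >= 8, which is what read-level matching requires.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

VALID_GROUPS = frozenset({
    "B_CELL", "IG_TRANSCRIPT", "T_CELL", "MUTATION", "DOUBLE_EXPRESSOR",
    "ABC_SIG", "GCB_SIG", "PMBL_SIG", "OTHER",
})
DNA_ALPHABET = frozenset("ACGT")

#: genes expected to carry two independent probe pairs in the default panel
DUAL_PAIR_GENES = ("AICDA", "BCL6", "MYC", "BCL2")

PANEL_COLUMNS = ("marker_id", "gene", "group", "pair_index", "left_seq",
                 "right_seq")


class PanelError(ValueError):
    """Raised when a panel file fails validation."""


@dataclass(frozen=True)
class MarkerProbe:
    """One half-probe pair reporting a single marker."""

    marker_id: str
    gene: str
    group: str
    pair_index: int
    left_seq: str
    right_seq: str

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise PanelError(
                f"probe {self.marker_id}: unknown group {self.group!r}")
        if self.pair_index < 1:
            raise PanelError(
                f"probe {self.marker_id}: pair_index must be >= 1")
        for name, seq in (("left_seq", self.left_seq),
                          ("right_seq", self.right_seq)):
            if not seq:
                raise PanelError(f"probe {self.marker_id}: empty {name}")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise PanelError(
                    f"probe {self.marker_id}: non-ACGT character "
                    f"{sorted(bad)} in {name}")

    @property
    def product(self) -> str:
        """Expected ligated insert carried by a read for this probe pair."""
        return self.left_seq + self.right_seq


@dataclass
class PanelDefinition:
    """An ordered, validated collection of marker probes."""

    probes: list[MarkerProbe]
    umi_length: int = 7
    adapters: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if not self.probes:
            raise PanelError("no probes")
        seen: dict[tuple[str, int], str] = {}
        for p in self.probes:
            key = (p.gene, p.pair_index)
            if key in seen:
                raise PanelError(
                    f"duplicate (gene, pair_index) {key}: markers "
                    f"{seen[key]} and {p.marker_id}")
            seen[key] = p.marker_id
        ids = [p.marker_id for p in self.probes]
        if len(ids) != len(set(ids)):
            raise PanelError("duplicate marker_id in panel")
        # variant probes (pair 1) of MUTATION loci need a reference (pair 2)
        mut = {p.gene: set() for p in self.probes if p.group == "MUTATION"}
        for p in self.probes:
            if p.group == "MUTATION":
                mut[p.gene].add(p.pair_index)
        for gene, idx in mut.items():
            if idx != {1, 2}:
                raise PanelError(
                    f"mutation locus {gene}: expected variant (pair 1) and "
                    f"reference (pair 2) probes, found pair_index {sorted(idx)}")

    @property
    def marker_ids(self) -> list[str]:
        return [p.marker_id for p in self.probes]

    @property
    def expression_probes(self) -> list[MarkerProbe]:
        return [p for p in self.probes if p.group != "MUTATION"]

    @property
    def expression_markers(self) -> list[str]:
        """Distinct expression genes, in panel order (dual pairs collapse)."""
        out: list[str] = []
        for p in self.expression_probes:
            if p.gene not in out:
                out.append(p.gene)
        return out

    @property
    def n_markers(self) -> int:
        """Number of distinct expression markers (137 for the default panel)."""
        return len(self.expression_markers)

    @property
    def dual_pair_genes(self) -> list[str]:
        counts: dict[str, int] = {}
        for p in self.expression_probes:
            counts[p.gene] = counts.get(p.gene, 0) + 1
        return [g for g, n in counts.items() if n > 1]

    @property
    def mutation_loci(self) -> list[str]:
        out: list[str] = []
        for p in self.probes:
            if p.group == "MUTATION" and p.gene not in out:
                out.append(p.gene)
        return out

    def probe(self, marker_id: str) -> MarkerProbe:
        for p in self.probes:
            if p.marker_id == marker_id:
                return p
        raise KeyError(marker_id)


def load_panel(path: str | Path, umi_length: int = 7) -> PanelDefinition:
    """Load a TSV panel file (UTF-8, ``#`` comment lines permitted).

    Columns: marker_id, gene, group, pair_index, left_seq, right_seq.
    Raises :class:`PanelError` with the offending line number on bad input.
    """
    path = Path(path)
    probes: list[MarkerProbe] = []
    with open(path, encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = set(PANEL_COLUMNS) - set(header)
                if missing:
                    raise PanelError(
                        f"{path}: header missing columns {sorted(missing)}")
                continue
            row = dict(zip(header, fields))
            try:
                probe = MarkerProbe(
                    marker_id=row["marker_id"],
                    gene=row["gene"],
                    group=row["group"],
                    pair_index=int(row["pair_index"]),
                    left_seq=row["left_seq"].upper(),
                    right_seq=row["right_seq"].upper(),
                )
            except (KeyError, ValueError) as exc:
                if isinstance(exc, PanelError):
                    raise PanelError(f"{path}:{lineno}: {exc}") from None
                raise PanelError(f"{path}:{lineno}: malformed row ({exc})") \
                    from None
            probes.append(probe)
    if header is None:
        raise PanelError(f"{path}: empty file, no header")
    if not probes:
        raise PanelError(f"{path}: no probes")
    try:
        return PanelDefinition(probes=probes, umi_length=umi_length)
    except PanelError as exc:
        raise PanelError(f"{path}: {exc}") from None


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    """Write a panel back to TSV; round-trips with :func:`load_panel`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for p in panel.probes:
            fh.write("\t".join([p.marker_id, p.gene, p.group,
                                str(p.pair_index), p.left_seq,
                                p.right_seq]) + "\n")


def ligation_products(panel: PanelDefinition) -> dict[str, str]:
    """Expected ligated insert per marker_id.

    Raises :class:`PanelError` if two probe pairs share an identical product
    (an ambiguous panel cannot be demultiplexed at read level).
    """
    products: dict[str, str] = {}
    seen: dict[str, str] = {}
    for p in panel.probes:
        prod = p.product
        if prod in seen:
            raise PanelError(
                f"ambiguous panel: probes {seen[prod]} and {p.marker_id} "
                "share an identical ligation product")
        seen[prod] = p.marker_id
        products[p.marker_id] = prod
    return products


def write_products_fasta(panel: PanelDefinition, path: str | Path) -> None:
    """Export expected ligation products as FASTA (one record per marker)."""
    with open(path, "w", encoding="utf-8") as fh:
        for marker_id, product in ligation_products(panel).items():
            fh.write(f">{marker_id}\n{product}\n")


def default_panel() -> PanelDefinition:
    """The packaged 137-marker default panel."""
    ref = importlib.resources.files("rtmis.data") / "default_panel.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_panel(path)
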