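"""Membrane-protein topology annotations and their two text dialects.

A topology annotation assigns every residue of a protein to one of a small
set of labels — ``inside`` (cytosolic), ``outside`` (luminal/extracellular),
``TMhelix`` (membrane-spanning), or ``signal`` — as produced by topology
predictors in the DeepTMHMM family.  Two on-disk dialects are supported:

* **gff3** — a GFF3-like block per protein::

      # P0001
      P0001\tinside\t1\t292
      P0001\tTMhelix\t293\t310
      P0001\toutside\t311\t317

* **three_line** — a FASTA-like record::

      >P0001 | TM=1
      MSA...sequence...
      IIII...MMMM...OOO

  with one topology character per residue over ``{I, O, M, S}``.

Coordinates are 1-based inclusive throughout, native to GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

__all__ = [
    "Segment",
    "TopologyAnnotation",
    "TopologyParseError",
    "parse_topology",
    "write_topology",
]

# canonical label set; parsers fold synonyms (e.g. "periplasm") onto these
LABELS = ("inside", "outside", "TMhelix", "signal")

_LABEL_ALIASES = {
    "inside": "inside",
    "outside": "outside",
    "tmhelix": "TMhelix",
    "signal": "signal",
    "periplasm": "outside",
    "membrane": "TMhelix",
}

_LABEL_TO_CHAR = {"inside": "I", "outside": "O", "TMhelix": "M", "signal": "S"}
_CHAR_TO_LABEL = {v: k for k, v in _LABEL_TO_CHAR.items()}


class TopologyParseError(ValueError):
    """Raised when a topology file violates the tiling contract."""


@dataclass(frozen=True)
class Segment:
    label: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown topology label {self.label!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad segment interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TopologyAnnotation:
    """Ordered segments tiling ``[1, length]`` without gaps or overlaps."""

    protein_id: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def length(self) -> int:
        return self.segments[-1].end if self.segments else 0

    @property
    def n_tmds(self) -> int:
        return sum(1 for s in self.segments if s.label == "TMhelix")

    def validate(self) -> None:
        pos = 1
        for seg in self.segments:
            if seg.start != pos:
                kind = "gap" if seg.start > pos else "overlap"
                raise TopologyParseError(
                    f"{self.protein_id}: {kind} at residue {min(pos, seg.start)} "
                    f"(segment {seg.label} {seg.start}-{seg.end}, expected start {pos})"
                )
            pos = seg.end + 1

    def label_string(self) -> str:
        return "".join(_LABEL_TO_CHAR[s.label] * s.length for s in self.segments)


def _annotation_from_labels(protein_id: str, labels: str) -> TopologyAnnotation:
    segs: list[Segment] = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        try:
            lab = _CHAR_TO_LABEL[labels[i]]
        except KeyError:
            raise TopologyParseError(
                f"{protein_id}: unknown topology character {labels[i]!r} at residue {i + 1}"
            ) from None
        segs.append(Segment(lab, i + 1, j))
        i = j
    return TopologyAnnotation(protein_id, segs)


# ---------------------------------------------------------------------------
# parsing

def _parse_gff3(text: str) -> list[TopologyAnnotation]:
    out: list[TopologyAnnotation] = []
    current_id: str | None = None
    segs: list[Segment] = []

    def flush() -> None:
        nonlocal current_id, segs
        if current_id is not None:
            out.append(TopologyAnnotation(current_id, segs))
        current_id, segs = None, []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            header = line.lstrip("#").strip()
            if header.lower().startswith("protein"):  # "# protein P0001" style
                header = header.split(None, 1)[1] if " " in header else ""
            if header:
                flush()
                current_id = header
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            parts = line.split()
        if len(parts) != 4:
            raise TopologyParseError(f"line {lineno}: expected 4 fields, got {len(parts)}")
        pid, label, start, end = parts
        label_norm = _LABEL_ALIASES.get(label.lower())
        if label_norm is None:
            raise TopologyParseError(f"line {lineno}: unknown label {label!r}")
        if current_id is None:
            current_id = pid
        elif pid != current_id:
            flush()
            current_id = pid
        try:
            seg = Segment(label_norm, int(start), int(end))
        except ValueError as exc:
            raise TopologyParseError(f"line {lineno} ({pid}): {exc}") from None
        segs.append(seg)
    flush()
    return out


def _parse_three_line(text: str) -> list[TopologyAnnotation]:
    out: list[TopologyAnnotation] = []
    lines = [ln for ln in (l.rstrip() for l in text.splitlines()) if ln]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise TopologyParseError(f"expected '>' header, got {lines[i]!r}")
        header = lines[i][1:].strip()
        pid = header.split("|")[0].strip().split()[0]
        if i + 2 >= len(lines):
            raise TopologyParseError(f"{pid}: truncated three-line record")
        seq, labels = lines[i + 1].strip(), lines[i + 2].strip()
        if len(seq) != len(labels):
            raise TopologyParseError(
                f"{pid}: sequence length {len(seq)} != label string length {len(labels)}"
            )
        out.append(_annotation_from_labels(pid, labels))
        i += 3
    return out


def parse_topology(
    text: str, dialect: Literal["gff3", "three_line", "auto"] = "auto"
) -> list[TopologyAnnotation]:
    """Parse topology annotations from either supported dialect.

    With ``dialect="auto"`` the first non-blank character decides: ``>`` means
    the three-line dialect, anything else the GFF3-like dialect.  Every
    annotation is validated against the tiling invariant; violations raise
    :class:`TopologyParseError` naming the protein and residue position.
    """
    stripped = text.lstrip()
    if not stripped:
        raise TopologyParseError("empty topology input")
    if dialect == "auto":
        dialect = "three_line" if stripped.startswith(">") else "gff3"
    if dialect == "gff3":
        return _parse_gff3(text)
    if dialect == "three_line":
        return _parse_three_line(text)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# writing

def write_topology(
    annotations: Iterable[TopologyAnnotation],
    dialect: Literal["gff3", "three_line"],
    sequences: dict[str, str] | None = None,
) -> str:
    """Serialize annotations; the three-line dialect needs the sequences."""
    anns = list(annotations)
    if dialect == "gff3":
        blocks = []
        for ann in anns:
            lines = [f"# {ann.protein_id}"]
            lines += [
                f"{ann.protein_id}\t{s.label}\t{s.start}\t{s.end}" for s in ann.segments
            ]
            blocks.append("\n".join(lines))
        return "\n".join(blocks) + "\n"
    if dialect == "three_line":
        if sequences is None:
            raise ValueError("three_line dialect requires sequences")
        blocks = []
        for ann in anns:
            seq = sequences[ann.protein_id]
            if len(seq) != ann.length:
                raise ValueError(
                    f"{ann.protein_id}: sequence length {len(seq)} != topology length {ann.length}"
                )
            blocks.append(f">{ann.protein_id} | TM={ann.n_tmds}\n{seq}\n{ann.label_string()}")
        return "\n".join(blocks) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")
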