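"""Reference annotation model: hairpins, mature miRNAs and arm labels.

Mature miRNAs are located on their precursor hairpins by exact substring
search, giving every mature a hairpin-local coordinate frame (0-based,
half-open) used by the isomiR classifier and the arm-usage analysis.
Identical mature sequences annotated at several loci are collapsed into a
single *expression unit* so read counts are never double-assigned.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._seq import to_rna, unify

log = logging.getLogger(__name__)

ARM_5P = "5p"
ARM_3P = "3p"
ARM_NONE = "unlabeled"

# miRBase-style name: species prefix, family core, locus letter(s),
# optional numeric locus variant, optional arm suffix.
_NAME_RE = re.compile(
    r"^(?:(?P<species>[a-zA-Z]{3,4})-)?"
    r"(?P<core>(?:mir|let|lin)-?\d+)"
    r"(?P<letters>[a-z]*)"
    r"(?:[-.]\d+)?"
    r"(?:-(?P<arm>[35]p))?$",
    re.IGNORECASE,
)


def parse_mirna_name(name: str) -> tuple[str, str]:
    """Split a miRBase-style mature name into (family, arm).

    ``ath-miR160a-5p`` -> (``miR160``, ``5p``); ``ath-miR168a`` -> (``miR168``,
    ``unlabeled``).  Names that do not look miRBase-like fall back to the full
    name as family with no arm label.
    """
    m = _NAME_RE.match(name)
    if not m:
        return name, ARM_NONE
    core = m.group("core")
    # normalise capitalisation of the family core: miR160, let-7 ...
    if core.lower().startswith("mir"):
        core = "miR" + core[3:]
    arm = m.group("arm")
    return core, (arm.lower() if arm else ARM_NONE)


def _name_stem(name: str) -> str:
    """Case-insensitive stem used to pair a mature with its hairpin."""
    s = name.lower()
    for suffix in ("-5p", "-3p"):
        if s.endswith(suffix):
            s = s[: -len(suffix)]
    return s


@dataclass(frozen=True)
class MatureAnnotation:
    """One mature miRNA located on one hairpin precursor."""

    name: str
    family: str
    arm: str  # one of {"5p", "3p", "unlabeled"}
    hairpin_id: str
    start: int  # 0-based on hairpin
    end: int  # half-open
    sequence: str  # internal DNA alphabet

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad coordinates for {self.name}: [{self.start}, {self.end})")


@dataclass
class ReferencePools:
    """Genome plus the ordered contaminant class pools.

    The pool order is the order of the sequential classification; it is part
    of the analysis definition, not an implementation detail.
    """

    genome: dict[str, str]
    class_pools: list[tuple[str, dict[str, str]]]

    def __post_init__(self) -> None:
        self.genome = {k: unify(v) for k, v in self.genome.items()}
        self.class_pools = [
            (name, {k: unify(v) for k, v in pool.items()}) for name, pool in self.class_pools
        ]


@dataclass
class AnnotationIndex:
    hairpins: dict[str, str]
    matures: list[MatureAnnotation]
    orphans: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.by_hairpin: dict[str, list[MatureAnnotation]] = {}
        for m in self.matures:
            self.by_hairpin.setdefault(m.hairpin_id, []).append(m)
        # collapse identical mature sequences into one expression unit
        seq_to_names: dict[str, list[str]] = {}
        for m in self.matures:
            seq_to_names.setdefault(m.sequence, []).append(m.name)
        self.unit_of_sequence: dict[str, str] = {
            seq: min(names) for seq, names in seq_to_names.items()
        }
        self.unit_members: dict[str, list[str]] = {
            min(names): sorted(names) for names in seq_to_names.values()
        }
        self.unit_sequence: dict[str, str] = {
            unit: seq for seq, unit in self.unit_of_sequence.items()
        }
        by_name = {m.name: m for m in self.matures}
        self.mature_by_name = by_name
        self.unit_family: dict[str, str] = {
            unit: by_name[unit].family for unit in self.unit_members
        }

    @property
    def units(self) -> list[str]:
        return sorted(self.unit_members)

    def unit_of(self, mature_name: str) -> str:
        return self.unit_of_sequence[self.mature_by_name[mature_name].sequence]


def load_annotation(mature_fasta: str | Path, hairpin_fasta: str | Path) -> AnnotationIndex:
    """Index mature miRNAs on their hairpins from miRBase-style FASTA files.

    Coordinates come from exact substring search of the mature in the hairpin
    whose identifier shares the mature's name stem; the leftmost occurrence
    wins (with a warning if several exist).  Matures with no locatable
    hairpin are kept on an orphan list and excluded from downstream
    coordinate-based analyses.
    """
    hairpins: dict[str, str] = {}
    for rec in SeqIO.parse(str(hairpin_fasta), "fasta"):
        hairpins[rec.id] = unify(str(rec.seq))
    if not hairpins:
        raise ValueError(f"no hairpin records parsed from {hairpin_fasta}")

    stem_to_hairpins: dict[str, list[str]] = {}
    for hid in hairpins:
        stem_to_hairpins.setdefault(_name_stem(hid), []).append(hid)

    matures: list[MatureAnnotation] = []
    orphans: list[str] = []
    n_mature = 0
    for rec in SeqIO.parse(str(mature_fasta), "fasta"):
        n_mature += 1
        seq = unify(str(rec.seq))
        family, arm = parse_mirna_name(rec.id)
        placed = False
        for hid in stem_to_hairpins.get(_name_stem(rec.id), []):
            hp = hairpins[hid]
            pos = hp.find(seq)
            if pos == -1:
                continue
            if hp.find(seq, pos + 1) != -1:
                log.warning(
                    "mature %s occurs at multiple positions in hairpin %s; using leftmost",
                    rec.id,
                    hid,
                )
            matures.append(
                MatureAnnotation(
                    name=rec.id,
                    family=family,
                    arm=arm,
                    hairpin_id=hid,
                    start=pos,
                    end=pos + len(seq),
                    sequence=seq,
                )
            )
            placed = True
            break
        if not placed:
            orphans.append(rec.id)
            log.warning("mature %s has no matching hairpin; recorded as orphan", rec.id)
    if n_mature == 0:
        raise ValueError(f"no mature records parsed from {mature_fasta}")
    return AnnotationIndex(hairpins=hairpins, matures=matures, orphans=orphans)


BOTH_ARMS = "both_arms"
ONE_ARM_5P = "one_arm_5p"
ONE_ARM_3P = "one_arm_3p"
NO_ARM = "no_arm"


def arm_category(hairpin_id: str, index: AnnotationIndex) -> str:
    """Arm-annotation category of a hairpin: both, a single labeled arm, or none."""
    if hairpin_id not in index.hairpins:
        raise KeyError(f"hairpin {hairpin_id!r} not in index")
    arms = {m.arm for m in index.by_hairpin.get(hairpin_id, [])}
    has5, has3 = ARM_5P in arms, ARM_3P in arms
    if has5 and has3:
        return BOTH_ARMS
    if has5:
        return ONE_ARM_5P
    if has3:
        return ONE_ARM_3P
    return NO_ARM


def annotation_table(index: AnnotationIndex) -> pd.DataFrame:
    """Flat per-mature table (sequences reported in RNA alphabet)."""
    rows = [
        {
            "name": m.name,
            "family": m.family,
            "arm": m.arm,
            "hairpin": m.hairpin_id,
            "start": m.start,
            "end": m.end,
            "sequence": to_rna(m.sequence),
        }
        for m in index.matures
    ]
    return pd.DataFrame(rows, columns=["name", "family", "arm", "hairpin", "start", "end", "sequence"])


def write_annotation_tsv(index: AnnotationIndex, path: str | Path) -> None:
    annotation_table(index).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path, hairpins: dict[str, str]) -> AnnotationIndex:
    """Rebuild an index from its TSV report plus the hairpin sequences."""
    df = pd.read_csv(path, sep="\t")
    matures = [
        MatureAnnotation(
            name=r["name"],
            family=r["family"],
            arm=r["arm"],
            hairpin_id=r["hairpin"],
            start=int(r["start"]),
            end=int(r["end"]),
            sequence=unify(r["sequence"]),
        )
        for r in df.to_dict("records")
    ]
    return AnnotationIndex(hairpins={k: unify(v) for k, v in hairpins.items()}, matures=matures)
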