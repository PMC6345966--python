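"""Synthetic small-RNA study generator with a full ground-truth manifest.

Emulates the structure of an altitudinal common-garden small-RNA study:
three populations (low / mid / high altitude) sampled in the field (FD)
and regrown in a glasshouse (GH), plus a reference-accession GH control.
The generator builds

* a random genome with embedded miRNA hairpins (perfect inverted repeats,
  stem 30 bp, so they are guaranteed foldable), contaminant pools
  (cDNA/t+rRNA/sno+snRNA/tasiRNA-like) and gene models;
* miRBase-style mature/hairpin FASTA with 5p/3p/unlabeled arm annotation;
* per-library FASTQ reads: miRNA reads drawn per-unit from a log-normal
  abundance distribution with planted population / condition fold changes
  (including monotone-with-altitude units), an isomiR category mixture with
  a 3' tailing base composition containing no guanosine, sibling arm reads
  at planted 5p:3p ratios, genomic background with condition-specific
  length modes (21 nt field-like, 24 nt glasshouse-like), contaminant
  fragments, adapter-only, low-quality and out-of-size reads;
* a site x bioclimatic-variable table with a monotone altitude gradient
  (temperature falling, radiation rising with altitude);
* a :class:`TruthManifest` recording every planted quantity so recovery
  can be scored without re-derivation.

Everything is driven by one integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import revcomp, to_rna
from .annotation import ARM_3P, ARM_5P, ARM_NONE, AnnotationIndex, MatureAnnotation, ReferencePools
from .isomir import (
    BOTH_END,
    CANONICAL,
    CATEGORIES,
    NONTEMPLATE_3P,
    SHIFTED,
    START_SITE,
    SUBSTITUTION,
    TEMPLATE_3P,
)

BASES = "ACGT"
POPULATIONS = ("Deh", "Mun", "Chit")
ALTITUDES_M = {"Deh": 700, "Mun": 2000, "Chit": 3400}
CONDITIONS = ("FD", "GH")

# fraction of the library in each read class, by growing condition
CLASS_FRACTIONS = {
    "FD": {"mirna": 0.30, "background": 0.43, "contaminant": 0.20,
           "low_quality": 0.02, "empty": 0.01, "oversize": 0.04},
    "GH": {"mirna": 0.25, "background": 0.48, "contaminant": 0.20,
           "low_quality": 0.02, "empty": 0.01, "oversize": 0.04},
}


@dataclass
class GeneratorConfig:
    seed: int = 0
    # reference geometry
    n_both_arm: int = 10
    n_single_5p: int = 8
    n_single_3p: int = 8
    n_unlabeled: int = 6
    stem_len: int = 30
    loop_len: int = 8
    pad3_len: int = 6
    n_chrom: int = 2
    chrom_len: int = 15000
    # study design
    library_size: int = 600_000
    include_col0: bool = True
    # abundance model
    abundance_sigma: float = 0.45
    # planted effects
    n_monotone_up: int = 5
    monotone_up_weight: float = 0.15
    monotone_up_multipliers: tuple[float, float, float] = (1.0, 4.0, 16.0)
    n_monotone_down: int = 1
    monotone_down_weight: float = 1.6
    monotone_down_multipliers: tuple[float, float, float] = (1.0, 0.25, 0.0625)
    n_de_units: int = 6
    de_multiplier: float = 2.5
    n_condition_hairpins: int = 6  # both-arm hairpins scaled jointly in GH
    n_condition_units: int = 3  # additional single-arm units
    condition_multiplier: float = 4.0
    n_pop_specific: int = 3  # expressed in exactly one population
    n_col0_units: int = 2
    col0_multiplier: float = 2.0
    # isomiR model
    isomir_mixture: dict = field(
        default_factory=lambda: {
            CANONICAL: 0.78,
            NONTEMPLATE_3P: 0.09,
            TEMPLATE_3P: 0.07,
            BOTH_END: 0.03,
            SHIFTED: 0.015,
            SUBSTITUTION: 0.01,
            START_SITE: 0.005,
        }
    )
    nta_weights: dict = field(default_factory=lambda: {"A": 0.32, "C": 0.30, "U": 0.38, "G": 0.0})
    arm_ratio_log2_range: tuple[float, float] = (-2.0, 2.0)
    # background / contaminants / novel locus
    background_mode: dict = field(default_factory=lambda: {"FD": 21, "GH": 24})
    background_sd: float = 1.0
    contaminant_weights: dict = field(
        default_factory=lambda: {"cDNA": 0.30, "t_rRNA": 0.40, "sno_snRNA": 0.15, "tasiRNA": 0.15}
    )
    novel_background_fraction: float = 0.01
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter

    def __post_init__(self) -> None:
        total = sum(self.isomir_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"isomiR mixture must sum to 1, got {total}")
        if abs(sum(self.nta_weights.values()) - 1.0) > 1e-9:
            raise ValueError("NTA base weights must sum to 1")

    @property
    def libraries(self) -> list[str]:
        libs = [f"{p}_{c}" for c in CONDITIONS for p in POPULATIONS]
        if self.include_col0:
            libs.append("Col0_GH")
        return libs

    @property
    def design(self) -> dict[str, tuple[str, str]]:
        d = {f"{p}_{c}": (p, c) for c in CONDITIONS for p in POPULATIONS}
        if self.include_col0:
            d["Col0_GH"] = ("Col0", "GH")
        return d


@dataclass
class SyntheticReference:
    genome: dict[str, str]
    hairpins: dict[str, str]
    matures: list[MatureAnnotation]
    pools: dict[str, dict[str, str]]  # class name -> sequences
    cdna: dict[str, str]
    gff3: str
    novel: dict  # chrom/start/end/mature/precursor span info
    free_intervals: dict[str, list[tuple[int, int]]]
    hairpin_loci: dict[str, tuple[str, int, int]]

    def annotation_index(self) -> AnnotationIndex:
        return AnnotationIndex(hairpins=dict(self.hairpins), matures=list(self.matures))

    def reference_pools(self) -> ReferencePools:
        return ReferencePools(
            genome=dict(self.genome),
            class_pools=[
                ("cDNA", dict(self.cdna)),
                ("t_rRNA", dict(self.pools["t_rRNA"])),
                ("sno_snRNA", dict(self.pools["sno_snRNA"])),
                ("tasiRNA", dict(self.pools["tasiRNA"])),
            ],
        )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        def fasta(path: Path, records: dict[str, str], rna: bool = False) -> None:
            with open(path, "w") as fh:
                for name, seq in records.items():
                    fh.write(f">{name}\n{to_rna(seq) if rna else seq}\n")

        paths["genome"] = out / "genome.fa"
        fasta(paths["genome"], self.genome)
        paths["hairpin"] = out / "hairpin.fa"
        fasta(paths["hairpin"], self.hairpins, rna=True)
        paths["mature"] = out / "mature.fa"
        fasta(paths["mature"], {m.name: m.sequence for m in self.matures}, rna=True)
        for pool in ("t_rRNA", "sno_snRNA", "tasiRNA"):
            paths[pool] = out / f"{pool}.fa"
            fasta(paths[pool], self.pools[pool])
        paths["cDNA"] = out / "cDNA.fa"
        fasta(paths["cDNA"], self.cdna)
        paths["gff3"] = out / "genes.gff3"
        paths["gff3"].write_text(self.gff3)
        return paths


@dataclass
class TruthManifest:
    design: dict[str, tuple[str, str]]
    unit_weights: dict[str, float]
    pop_multipliers: dict[str, dict[str, float]]  # unit -> population -> x
    cond_multipliers: dict[str, float]  # unit -> GH multiplier
    monotone_up: list[str]
    monotone_down: list[str]
    de_units: list[str]
    condition_units: list[str]
    pop_specific: dict[str, str]  # unit -> population
    arm_ratio_log2: dict[str, float]  # both-arm hairpin -> planted log2(5p/3p)
    isomir_mixture: dict[str, float]
    nta_weights: dict[str, float]
    class_counts: dict[str, dict[str, int]]  # library -> class -> reads drawn
    expected_proportion: dict[str, dict[str, float]]  # library -> unit -> p within miRNA class
    true_unit_counts: dict[str, dict[str, int]]  # library -> unit -> miRNA reads drawn
    p_labeled: float  # chance a miRNA read is countable as miRNA by exact matching
    p_cleaned: float  # chance a miRNA read survives into the cleaned fraction
    novel_mature: str
    altitudes: dict[str, int]

    def expected_labeled_count(self, unit: str, library: str) -> float:
        return (
            self.class_counts[library]["mirna"]
            * self.expected_proportion[library][unit]
            * self.p_labeled
        )

    def expected_cleaned_total(self, library: str) -> float:
        cc = self.class_counts[library]
        return cc["mirna"] * self.p_cleaned + cc["background"]

    def expected_rpm(self, unit: str, library: str) -> float:
        return 1e6 * self.expected_labeled_count(unit, library) / self.expected_cleaned_total(library)

    def expected_log2fc(self, unit: str, lib_a: str, lib_b: str) -> float:
        return float(np.log2(self.expected_rpm(unit, lib_b) / self.expected_rpm(unit, lib_a)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(stream)))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def generate_reference(cfg: GeneratorConfig) -> SyntheticReference:
    """Build genome, hairpins, annotation, pools and gene models."""
    rng = _rng(cfg.seed, 0)
    stem, loop, pad = cfg.stem_len, cfg.loop_len, cfg.pad3_len

    def build_hairpin() -> str:
        """Perfect inverted repeat: stem + loop + revcomp(stem) + 3' pad."""
        arm = _random_seq(rng, stem)
        loop_seq = _random_seq(rng, loop)
        return arm + loop_seq + revcomp(arm) + _random_seq(rng, pad)

    hairpins: dict[str, str] = {}
    matures: list[MatureAnnotation] = []
    plan = (
        [("both", None)] * cfg.n_both_arm
        + [("single", ARM_5P)] * cfg.n_single_5p
        + [("single", ARM_3P)] * cfg.n_single_3p
        + [("single", ARM_NONE)] * cfg.n_unlabeled
    )
    for i, (kind, arm) in enumerate(plan, start=101):
        hid = f"ath-MIR9{i}"
        while True:
            hp = build_hairpin()
            L5 = int(rng.choice([20, 21, 22], p=[0.25, 0.5, 0.25]))
            s5 = 5
            seq5 = hp[s5 : s5 + L5]
            # star of the 5p mature under the 2-nt 3' overhang convention
            # (pairing i <-> 2*stem+loop-1-i inside the stem)
            hp_core = 2 * stem + loop
            lo = hp_core - (s5 + L5)
            hi = hp_core - 1 - s5
            s3, e3 = lo + 2, hi + 3
            seq3 = hp[s3:e3]
            ok = (
                hp.find(seq5) == s5
                and hp.rfind(seq5) == s5
                and hp.find(seq3) == s3
                and hp.rfind(seq3) == s3
                and seq5 != seq3
            )
            if ok:
                break
        hairpins[hid] = hp
        stem_name = hid.replace("MIR", "miR")
        if kind == "both":
            matures.append(MatureAnnotation(f"{stem_name}-5p", "", ARM_5P, hid, s5, s5 + L5, seq5))
            matures.append(MatureAnnotation(f"{stem_name}-3p", "", ARM_3P, hid, s3, e3, seq3))
        elif arm == ARM_5P:
            matures.append(MatureAnnotation(f"{stem_name}-5p", "", ARM_5P, hid, s5, s5 + L5, seq5))
        elif arm == ARM_3P:
            matures.append(MatureAnnotation(f"{stem_name}-3p", "", ARM_3P, hid, s3, e3, seq3))
        else:
            matures.append(MatureAnnotation(stem_name, "", ARM_NONE, hid, s5, s5 + L5, seq5))
    # family / arm labels come from the names at load time; rebuild records
    from .annotation import parse_mirna_name

    matures = [
        MatureAnnotation(m.name, parse_mirna_name(m.name)[0], m.arm, m.hairpin_id, m.start, m.end, m.sequence)
        for m in matures
    ]
    seqs = [m.sequence for m in matures]
    if len(set(seqs)) != len(seqs):
        raise RuntimeError("mature sequence collision in synthetic reference; change the seed")

    # novel (unannotated) hairpin: same construction, mature at [5, 26)
    novel_arm = _random_seq(rng, stem)
    novel_hp = novel_arm + _random_seq(rng, loop) + revcomp(novel_arm) + _random_seq(rng, pad)
    novel_mature = novel_hp[5:26]

    # contaminant pools
    pools = {
        "t_rRNA": {f"trRNA-{j}": _random_seq(rng, int(rng.integers(70, 121))) for j in range(6)},
        "sno_snRNA": {f"snoRNA-{j}": _random_seq(rng, 100) for j in range(3)},
        "tasiRNA": {f"TAS-{j}": _random_seq(rng, 80) for j in range(3)},
    }

    # gene models: exon1 - intron - exon2; the novel hairpin sits in the
    # first gene's intron, cDNA = spliced exons
    genes = []
    for g in range(4):
        exon1, exon2 = _random_seq(rng, 300), _random_seq(rng, 300)
        if g == 0:
            intron = _random_seq(rng, 150) + novel_hp + _random_seq(rng, 150)
        else:
            intron = _random_seq(rng, 400)
        genes.append((f"gene{g + 1}", exon1, intron, exon2))
    cdna = {name: e1 + e2 for name, e1, _i, e2 in genes}

    # genome assembly: features separated by free spacer intervals
    features: list[tuple[str, str]] = []  # (kind, sequence)
    for hid, hp in hairpins.items():
        features.append((f"hairpin:{hid}", hp))
    for name, e1, intr, e2 in genes:
        features.append((f"gene:{name}", e1 + intr + e2))
    for pool in pools.values():
        for name, seq in pool.items():
            features.append((f"pool:{name}", seq))
    order = rng.permutation(len(features))

    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chrom)]
    per_chrom = int(np.ceil(len(features) / cfg.n_chrom))
    genome: dict[str, str] = {}
    free: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    feature_locus: dict[str, tuple[str, int, int]] = {}
    for ci, chrom in enumerate(chrom_names):
        parts: list[str] = []
        pos = 0
        for k in order[ci * per_chrom : (ci + 1) * per_chrom]:
            kind, seq = features[k]
            spacer = _random_seq(rng, int(rng.integers(150, 300)))
            free[chrom].append((pos, pos + len(spacer)))
            parts.append(spacer)
            pos += len(spacer)
            feature_locus[kind] = (chrom, pos, pos + len(seq))
            parts.append(seq)
            pos += len(seq)
        tail = _random_seq(rng, int(rng.integers(200, 400)))
        free[chrom].append((pos, pos + len(tail)))
        parts.append(tail)
        genome[chrom] = "".join(parts)

    # GFF3 (1-based inclusive)
    lines = ["##gff-version 3"]
    for name, e1, intr, e2 in genes:
        chrom, gs, ge = feature_locus[f"gene:{name}"]
        lines.append(f"{chrom}\t.\tgene\t{gs + 1}\t{ge}\t.\t+\t.\tID={name}")
        ex1_end = gs + len(e1)
        ex2_start = ge - len(e2)
        lines.append(f"{chrom}\t.\texon\t{gs + 1}\t{ex1_end}\t.\t+\t.\tID={name}.e1;Parent={name}")
        lines.append(f"{chrom}\t.\texon\t{ex2_start + 1}\t{ge}\t.\t+\t.\tID={name}.e2;Parent={name}")
    gff3 = "\n".join(lines) + "\n"

    g1 = genes[0]
    novel_offset = feature_locus["gene:gene1"][1] + len(g1[1]) + 150
    novel = {
        "chrom": feature_locus["gene:gene1"][0],
        "precursor_start": novel_offset,
        "precursor_end": novel_offset + len(novel_hp),
        "mature_start": novel_offset + 5,
        "mature_end": novel_offset + 26,
        "mature": novel_mature,
        "precursor": novel_hp,
    }

    hairpin_loci = {
        kind.split(":", 1)[1]: locus
        for kind, locus in feature_locus.items()
        if kind.startswith("hairpin:")
    }
    return SyntheticReference(
        genome=genome,
        hairpins=hairpins,
        matures=matures,
        pools=pools,
        cdna=cdna,
        gff3=gff3,
        novel=novel,
        free_intervals=free,
        hairpin_loci=hairpin_loci,
    )


def _labeled_and_cleaned_probability(
    mixture: dict[str, float],
    length_probs: dict[int, float] = {20: 0.25, 21: 0.5, 22: 0.25},
) -> tuple[float, float]:
    """Chance a miRNA read is (a) countable by exact mature containment and
    (b) genome-mapped and contaminant-free (cleaned), under the generator's
    variant rules.

    Shifted reads are genome-true but neither contain nor are contained in
    the mature; non-template tails and substitutions are absent from the
    genome; both-end reads (all pure template here) are containment-
    compatible only when their end offsets have opposite signs.  The
    admissible offset pairs depend on the mature length (the generator
    never emits reads outside the 18-28 nt size window), so the both-end
    fraction is averaged over the mature length distribution.
    """
    opposite = 0.0
    for L, w in length_probs.items():
        valid = [
            (o5, o3)
            for o5 in (-2, -1, 1, 2)
            for o3 in (-2, -1, 1, 2)
            if o5 != o3 and 18 <= L - o5 + o3 <= 28
        ]
        n_opp = sum(1 for o5, o3 in valid if (o5 > 0) != (o3 > 0))
        opposite += w * n_opp / len(valid)
    p_labeled = (
        mixture[CANONICAL]
        + mixture[TEMPLATE_3P]
        + mixture[START_SITE]
        + mixture[BOTH_END] * opposite
    )
    p_cleaned = (
        mixture[CANONICAL]
        + mixture[TEMPLATE_3P]
        + mixture[START_SITE]
        + mixture[BOTH_END]
        + mixture[SHIFTED]
    )
    return p_labeled, p_cleaned


def _synth_variant(
    rng: np.random.Generator,
    category: str,
    mature: MatureAnnotation,
    hairpin: str,
    nta_bases: list[str],
    nta_probs: list[float],
) -> str:
    """One read sequence of the requested isomiR category."""
    s, e = mature.start, mature.end
    if category == CANONICAL:
        return mature.sequence
    if category == SHIFTED:
        k = int(rng.choice([-2, -1, 1, 2]))
        return hairpin[s + k : e + k]
    if category == TEMPLATE_3P:
        k = int(rng.choice([-2, -1, 1, 2]))
        return hairpin[s : e + k]
    if category == START_SITE:
        k = int(rng.choice([-2, -1, 1, 2]))
        return hairpin[s + k : e]
    if category == BOTH_END:
        L = e - s
        while True:
            o5 = int(rng.choice([-2, -1, 1, 2]))
            o3 = int(rng.choice([-2, -1, 1, 2]))
            # stay inside the 18-28 nt size window or the read would be
            # removed by the size filter and distort the planted mixture
            if o5 != o3 and 18 <= L - o5 + o3 <= 28:
                return hairpin[s + o5 : e + o3]
    if category == NONTEMPLATE_3P:
        n_tail = int(rng.choice([1, 2], p=[0.7, 0.3]))
        template_next = hairpin[e] if e < len(hairpin) else None
        tail = ""
        for j in range(n_tail):
            while True:
                b = str(rng.choice(nta_bases, p=nta_probs))
                if j == 0 and b == template_next:
                    continue  # must disagree with the template continuation
                break
            tail += b
        return mature.sequence + tail
    if category == SUBSTITUTION:
        L = len(mature.sequence)
        pos = int(rng.integers(4, L - 7))  # central, and outside the 3'-tail window
        old = mature.sequence[pos]
        new = str(rng.choice([b for b in BASES if b != old]))
        return mature.sequence[:pos] + new + mature.sequence[pos + 1 :]
    raise ValueError(category)


def generate_libraries(
    cfg: GeneratorConfig, ref: SyntheticReference, out_dir: str | Path
) -> tuple[dict[str, Path], TruthManifest]:
    """Write one FASTQ per library and return the truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = ref.annotation_index()
    units = index.units
    rep = {u: index.mature_by_name[u] for u in units}
    rng = _rng(cfg.seed, 1)

    # --- planted abundance model -------------------------------------------------
    both_hairpins = sorted(
        h for h, ms in index.by_hairpin.items() if {m.arm for m in ms} == {ARM_5P, ARM_3P}
    )
    single_units = sorted(u for u in units if rep[u].hairpin_id not in both_hairpins)
    weights: dict[str, float] = {}
    arm_ratio_log2: dict[str, float] = {}
    for h in both_hairpins:
        w_h = float(np.exp(rng.normal(0.0, cfg.abundance_sigma)))
        r = float(rng.uniform(*cfg.arm_ratio_log2_range))
        arm_ratio_log2[h] = r
        rho = 2.0**r
        five = next(m for m in index.by_hairpin[h] if m.arm == ARM_5P)
        three = next(m for m in index.by_hairpin[h] if m.arm == ARM_3P)
        weights[index.unit_of(five.name)] = w_h * rho / (1 + rho)
        weights[index.unit_of(three.name)] = w_h / (1 + rho)
    for u in single_units:
        weights[u] = float(np.exp(rng.normal(0.0, cfg.abundance_sigma)))

    # deterministic role assignment over the single-arm units
    pool = list(single_units)
    take = lambda n: [pool.pop(0) for _ in range(n)]
    monotone_up = take(cfg.n_monotone_up)
    monotone_down = take(cfg.n_monotone_down)
    de_units = take(cfg.n_de_units)
    condition_single = take(cfg.n_condition_units)
    pop_specific_units = take(cfg.n_pop_specific)
    col0_units = take(cfg.n_col0_units)

    for u in monotone_up:
        weights[u] = cfg.monotone_up_weight
    for u in monotone_down:
        weights[u] = cfg.monotone_down_weight
    for u in condition_single:
        weights[u] = max(weights[u], 0.8)

    pop_mult: dict[str, dict[str, float]] = {u: {p: 1.0 for p in POPULATIONS} for u in units}
    for u in units:
        pop_mult[u]["Col0"] = 1.0
    for u in monotone_up:
        for p, m in zip(POPULATIONS, cfg.monotone_up_multipliers):
            pop_mult[u][p] = m
    for u in monotone_down:
        for p, m in zip(POPULATIONS, cfg.monotone_down_multipliers):
            pop_mult[u][p] = m
    de_patterns = [
        (1.0, cfg.de_multiplier, 1.0),
        (1.0, 1.0, cfg.de_multiplier),
        (cfg.de_multiplier, 1.0, 1.0),
        (1.0, 1.0 / cfg.de_multiplier, 1.0),
        (1.0, 1.0, 1.0 / cfg.de_multiplier),
        (1.0 / cfg.de_multiplier, 1.0, 1.0),
    ]
    for u, pattern in zip(de_units, de_patterns * 3):
        for p, m in zip(POPULATIONS, pattern):
            pop_mult[u][p] = m
    pop_specific: dict[str, str] = {}
    for u, p_home in zip(pop_specific_units, ("Chit", "Chit", "Mun")):
        pop_specific[u] = p_home
        for p in POPULATIONS:
            pop_mult[u][p] = 1.0 if p == p_home else 0.0
        pop_mult[u]["Col0"] = 0.0
    for u in col0_units:
        pop_mult[u]["Col0"] = cfg.col0_multiplier

    cond_mult: dict[str, float] = {u: 1.0 for u in units}
    cond_hairpins = both_hairpins[: cfg.n_condition_hairpins]
    condition_units: list[str] = []
    for j, h in enumerate(cond_hairpins):
        m = cfg.condition_multiplier if j % 2 == 0 else 1.0 / cfg.condition_multiplier
        for mat in index.by_hairpin[h]:
            u = index.unit_of(mat.name)
            cond_mult[u] = m
            condition_units.append(u)
    for j, u in enumerate(condition_single):
        cond_mult[u] = cfg.condition_multiplier if j % 2 == 0 else 1.0 / cfg.condition_multiplier
        condition_units.append(u)

    mixture = dict(cfg.isomir_mixture)
    p_labeled, p_cleaned = _labeled_and_cleaned_probability(mixture)
    nta_bases = sorted(cfg.nta_weights)
    nta_probs_dna = [cfg.nta_weights[b] for b in nta_bases]
    nta_bases_dna = [b.replace("U", "T") for b in nta_bases]

    # background sampling support
    free_support = []
    for chrom, intervals in ref.free_intervals.items():
        for s, e in intervals:
            if e - s >= 40:
                free_support.append((chrom, s, e))
    free_lens = np.array([e - s for _, s, e in free_support], dtype=float)
    free_probs = free_lens / free_lens.sum()

    cat_names = list(CATEGORIES)
    cat_probs = [mixture[c] for c in cat_names]
    cont_names = sorted(cfg.contaminant_weights)
    cont_probs = [cfg.contaminant_weights[c] for c in cont_names]
    cont_sources = {
        "cDNA": list(ref.cdna.values()),
        "t_rRNA": list(ref.pools["t_rRNA"].values()),
        "sno_snRNA": list(ref.pools["sno_snRNA"].values()),
        "tasiRNA": list(ref.pools["tasiRNA"].values()),
    }

    paths: dict[str, Path] = {}
    class_counts: dict[str, dict[str, int]] = {}
    expected_proportion: dict[str, dict[str, float]] = {}
    true_unit_counts: dict[str, dict[str, int]] = {}

    for lib_i, lib in enumerate(cfg.libraries):
        popn, cond = cfg.design[lib]
        lrng = _rng(cfg.seed, 2, lib_i)
        fracs = CLASS_FRACTIONS[cond]
        class_order = ["mirna", "background", "contaminant", "low_quality", "empty", "oversize"]
        n_class = lrng.multinomial(cfg.library_size, [fracs[c] for c in class_order])
        counts = dict(zip(class_order, (int(x) for x in n_class)))
        class_counts[lib] = counts

        raw_w = np.array(
            [weights[u] * pop_mult[u][popn] * (cond_mult[u] if cond == "GH" else 1.0) for u in units]
        )
        p_units = raw_w / raw_w.sum()
        expected_proportion[lib] = {u: float(p) for u, p in zip(units, p_units)}
        unit_draw = lrng.multinomial(counts["mirna"], p_units)
        true_unit_counts[lib] = {u: int(n) for u, n in zip(units, unit_draw)}

        reads: list[tuple[str, str]] = []  # (insert, quality-char)

        # miRNA reads per unit per isomiR category
        for u, n_u in zip(units, unit_draw):
            if n_u == 0:
                continue
            mat = rep[u]
            hp = index.hairpins[mat.hairpin_id]
            cat_draw = lrng.multinomial(n_u, cat_probs)
            for cat, n_c in zip(cat_names, cat_draw):
                for _ in range(int(n_c)):
                    seq = _synth_variant(lrng, cat, mat, hp, nta_bases_dna, nta_probs_dna)
                    reads.append((seq, "I"))

        # background: novel-locus reads plus free-interval fragments
        n_bg = counts["background"]
        n_novel = int(round(n_bg * cfg.novel_background_fraction))
        novel_hp = ref.novel["precursor"]
        for _ in range(n_novel):
            if lrng.random() < 0.85:
                reads.append((ref.novel["mature"], "I"))
            else:
                k = int(lrng.choice([-1, 1]))
                reads.append((novel_hp[5 + k : 26 + k], "I"))
        mode = cfg.background_mode[cond]

        def background_insert(rng_, length: int) -> str:
            while True:
                i = int(rng_.choice(len(free_support), p=free_probs))
                chrom, s, e = free_support[i]
                if e - s <= length:
                    continue
                start = int(rng_.integers(s, e - length))
                return ref.genome[chrom][start : start + length]

        bg_lengths = np.clip(np.rint(lrng.normal(mode, cfg.background_sd, size=n_bg - n_novel)), 18, 28)
        for L in bg_lengths:
            reads.append((background_insert(lrng, int(L)), "I"))

        # contaminant fragments
        cont_draw = lrng.multinomial(counts["contaminant"], cont_probs)
        for cname, n_c in zip(cont_names, cont_draw):
            sources = cont_sources[cname]
            for _ in range(int(n_c)):
                src = sources[int(lrng.integers(0, len(sources)))]
                L = min(int(lrng.integers(18, 29)), len(src))
                start = int(lrng.integers(0, len(src) - L + 1))
                reads.append((src[start : start + L], "I"))

        # junk classes
        for _ in range(counts["low_quality"]):
            reads.append((background_insert(lrng, 21), "#"))
        for _ in range(counts["empty"]):
            reads.append(("", "I"))
        oversize_lengths = [int(lrng.choice([16, 17, 29, 30, 31])) for _ in range(counts["oversize"])]
        for L in oversize_lengths:
            reads.append((background_insert(lrng, L), "I"))

        path = out / f"{lib}.fastq"
        with open(path, "w") as fh:
            for r_i, (insert, qchar) in enumerate(reads):
                read = insert + cfg.adapter
                fh.write(f"@{lib}:{r_i}\n{read}\n+\n{qchar * len(read)}\n")
        paths[lib] = path

    manifest = TruthManifest(
        design=cfg.design,
        unit_weights=weights,
        pop_multipliers=pop_mult,
        cond_multipliers=cond_mult,
        monotone_up=monotone_up,
        monotone_down=monotone_down,
        de_units=de_units,
        condition_units=condition_units,
        pop_specific=pop_specific,
        arm_ratio_log2=arm_ratio_log2,
        isomir_mixture=mixture,
        nta_weights=dict(cfg.nta_weights),
        class_counts=class_counts,
        expected_proportion=expected_proportion,
        true_unit_counts=true_unit_counts,
        p_labeled=p_labeled,
        p_cleaned=p_cleaned,
        novel_mature=ref.novel["mature"],
        altitudes=dict(ALTITUDES_M),
    )
    return paths, manifest


BIOCLIM_TEMPERATURE = [f"bio{k}" for k in range(1, 12)]
BIOCLIM_PRECIPITATION = [f"bio{k}" for k in range(12, 20)]


def generate_climate(cfg: GeneratorConfig) -> pd.DataFrame:
    """Site x variable table: 19 bioclim-style variables plus AT, AP, AR.

    Temperature-like variables fall strictly with altitude (a fixed lapse),
    radiation rises, precipitation peaks at the mid-altitude site — the
    classic monsoonal mid-slope maximum.
    """
    rng = _rng(cfg.seed, 3)
    sites = list(POPULATIONS)
    alt_km = np.array([ALTITUDES_M[s] / 1000.0 for s in sites])
    at = 26.0 - 5.5 * alt_km
    ap = np.array([900.0, 1400.0, 700.0])
    ar = 14.0 + 3.5 * alt_km
    data: dict[str, np.ndarray] = {}
    for var in BIOCLIM_TEMPERATURE:
        a = rng.uniform(-4.0, 4.0)
        b = rng.uniform(0.6, 1.4)
        data[var] = a + b * at + rng.normal(0.0, 0.3, size=len(sites))
    for var in BIOCLIM_PRECIPITATION:
        b = rng.uniform(0.5, 1.5)
        data[var] = b * ap + rng.normal(0.0, 20.0, size=len(sites))
    data["AT"] = at
    data["AP"] = ap
    data["AR"] = ar
    table = pd.DataFrame(data, index=pd.Index(sites, name="site"))
    return table
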