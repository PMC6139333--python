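"""Domain types and I/O for multilocus haplotype-alignment datasets.

The atomic unit is a :class:`LocusAlignment`: one locus's aligned haplotype
sequences, each tagged with the species it was sampled from.  A
:class:`MultilocusDataset` bundles many unlinked loci with a fixed, recorded
species order; that order determines the (1,2), (1,3), (2,3) pair ordering
used by every pairwise statistic downstream.

Sites containing ``N`` or ``-`` in *any* sequence of an alignment are excluded
from all site-based statistics (complete deletion); the retained-site mask is
exposed via :meth:`LocusAlignment.retained_sites`.  Site indices are 0-based
internally and 1-based in reports.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGTN-"
_BASE_CODE = {c: i for i, c in enumerate(ALPHABET)}
#: integer codes for the four unambiguous bases
ACGT = frozenset("ACGT")


class AlignmentError(ValueError):
    """Raised for ragged or otherwise malformed alignments."""


class SpeciesMapError(KeyError):
    """Raised when a sample id cannot be mapped to a species."""


@dataclass
class LocusAlignment:
    """Aligned haplotype sequences for one locus with species labels."""

    locus_id: str
    sequences: list[str]
    species_labels: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError(f"{self.locus_id}: empty alignment")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.locus_id}: ragged alignment, lengths {sorted(lengths)}"
            )
        if len(self.species_labels) != len(self.sequences):
            raise AlignmentError(
                f"{self.locus_id}: {len(self.sequences)} sequences but "
                f"{len(self.species_labels)} species labels"
            )
        bad = set("".join(self.sequences)) - set(ALPHABET)
        if bad:
            raise AlignmentError(f"{self.locus_id}: invalid characters {sorted(bad)}")
        if self.sample_ids is None:
            self.sample_ids = [f"{self.locus_id}_{i}" for i in range(len(self.sequences))]

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def species(self) -> list[str]:
        """Species present, in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.species_labels:
            seen.setdefault(s)
        return list(seen)

    def matrix(self) -> np.ndarray:
        """(n_sequences, length) int8 matrix coding A,C,G,T,N,- as 0..5."""
        out = np.empty((self.n_sequences, self.length), dtype=np.int8)
        for i, s in enumerate(self.sequences):
            out[i] = np.frombuffer(s.encode(), dtype=np.uint8)
        lut = np.full(256, -1, dtype=np.int8)
        for c, v in _BASE_CODE.items():
            lut[ord(c)] = v
        return lut[out.astype(np.intp)]

    def retained_sites(self) -> np.ndarray:
        """Boolean mask of sites free of N/- in every sequence."""
        return (self.matrix() < 4).all(axis=0)

    def retained_length(self) -> int:
        return int(self.retained_sites().sum())

    def indices_for(self, species: str) -> np.ndarray:
        idx = np.array([i for i, s in enumerate(self.species_labels) if s == species])
        if idx.size == 0:
            raise SpeciesMapError(f"species {species!r} not in locus {self.locus_id}")
        return idx

    def subset(self, species: Iterable[str]) -> "LocusAlignment":
        keep = set(species)
        idx = [i for i, s in enumerate(self.species_labels) if s in keep]
        return LocusAlignment(
            locus_id=self.locus_id,
            sequences=[self.sequences[i] for i in idx],
            species_labels=[self.species_labels[i] for i in idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class HaplotypeSpectrum:
    """Unique haplotype strings and their counts within one species."""

    species: str
    counts: dict[str, int]

    @property
    def n_haplotypes(self) -> int:
        return len(self.counts)

    @property
    def sample_size(self) -> int:
        return sum(self.counts.values())


def haplotype_spectrum(al: LocusAlignment, species: str) -> HaplotypeSpectrum:
    """Group one species' sequences by exact identity on retained sites."""
    idx = al.indices_for(species)
    mask = al.retained_sites()
    counts: Counter[str] = Counter()
    for i in idx:
        counts["".join(c for c, keep in zip(al.sequences[i], mask) if keep)] += 1
    return HaplotypeSpectrum(species=species, counts=dict(counts))


@dataclass
class MultilocusDataset:
    """A collection of unlinked loci over a fixed, ordered species set."""

    loci: list[LocusAlignment]
    species: list[str]
    provenance: str = "observed"  # observed | simulated
    truth: dict | None = None

    def __post_init__(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate locus ids in dataset")
        known = set(self.species)
        for l in self.loci:
            extra = set(l.species_labels) - known
            if extra:
                raise SpeciesMapError(
                    f"locus {l.locus_id}: unknown species {sorted(extra)}"
                )

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def species_pairs(self) -> list[tuple[str, str]]:
        """Pairs (1,2), (1,3), (2,3) in the recorded species order."""
        sp = self.species
        return [(sp[i], sp[j]) for i in range(len(sp)) for j in range(i + 1, len(sp))]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (sample_id, species); duplicated ids are rejected."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise SpeciesMapError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        sid, sp = parts
        if sid in mapping:
            raise SpeciesMapError(f"{path}:{lineno}: duplicated sample id {sid!r}")
        mapping[sid] = sp
    return mapping


def write_species_map(mapping: Mapping[str, str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{k}\t{v}\n" for k, v in mapping.items()))


def read_locus_fasta(
    path: str | Path, species_map: Mapping[str, str], locus_id: str | None = None
) -> LocusAlignment:
    """Read one locus's FASTA; every record id must appear in ``species_map``."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: empty or not FASTA")
    seqs, labels, ids = [], [], []
    for rec in records:
        if rec.id not in species_map:
            raise SpeciesMapError(f"{path}: sample id {rec.id!r} not in species map")
        seqs.append(str(rec.seq).upper())
        labels.append(species_map[rec.id])
        ids.append(rec.id)
    return LocusAlignment(
        locus_id=locus_id or Path(path).stem,
        sequences=seqs,
        species_labels=labels,
        sample_ids=ids,
    )


def write_locus_fasta(al: LocusAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for s, sid in zip(al.sequences, al.sample_ids)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_dataset(ds: MultilocusDataset, outdir: str | Path) -> Path:
    """Write FASTA-per-locus + species map TSV + YAML manifest (+ truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mapping: dict[str, str] = {}
    locus_files = []
    for al in ds.loci:
        fname = f"{al.locus_id}.fasta"
        write_locus_fasta(al, outdir / fname)
        locus_files.append(fname)
        for sid, sp in zip(al.sample_ids, al.species_labels):
            mapping.setdefault(sid, sp)
    write_species_map(mapping, outdir / "species_map.tsv")
    manifest = {
        "species": list(ds.species),
        "species_map": "species_map.tsv",
        "loci": locus_files,
        "provenance": ds.provenance,
    }
    if ds.truth is not None:
        (outdir / "truth.json").write_text(json.dumps(ds.truth, indent=2))
        manifest["truth"] = "truth.json"
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return outdir / "manifest.yaml"


def read_dataset(manifest_path: str | Path) -> MultilocusDataset:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.yaml"
    base = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    species_map = read_species_map(base / manifest["species_map"])
    loci = [read_locus_fasta(base / f, species_map) for f in manifest["loci"]]
    truth = None
    if manifest.get("truth"):
        truth = json.loads((base / manifest["truth"]).read_text())
    return MultilocusDataset(
        loci=loci,
        species=list(manifest["species"]),
        provenance=manifest.get("provenance", "observed"),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationConfig:
    min_sequences_per_species: int = 2
    max_missing_fraction: float = 0.5  # cap on proportion of masked sites


@dataclass
class ValidationReport:
    rows: list[dict] = field(default_factory=list)

    @property
    def usable(self) -> bool:
        return all(r["status"] == "pass" for r in self.rows)

    def to_tsv(self, path: str | Path) -> None:
        cols = ["locus_id", "status", "reasons"]
        lines = ["\t".join(cols)]
        for r in self.rows:
            lines.append("\t".join([r["locus_id"], r["status"], ";".join(r["reasons"])]))
        Path(path).write_text("\n".join(lines) + "\n")


def validate_dataset(
    ds: MultilocusDataset, config: ValidationConfig | None = None
) -> ValidationReport:
    """Per-locus pass/fail report; the dataset is unusable if any locus fails."""
    cfg = config or ValidationConfig()
    report = ValidationReport()
    for al in ds.loci:
        reasons = []
        present = Counter(al.species_labels)
        for sp in ds.species:
            n = present.get(sp, 0)
            if n < cfg.min_sequences_per_species:
                reasons.append(
                    f"insufficient within-species sample: {sp} has {n} "
                    f"(min {cfg.min_sequences_per_species})"
                )
        masked = 1.0 - al.retained_length() / al.length
        if masked > cfg.max_missing_fraction:
            reasons.append(
                f"masked site fraction {masked:.2f} exceeds cap {cfg.max_missing_fraction}"
            )
        report.rows.append(
            {
                "locus_id": al.locus_id,
                "status": "pass" if not reasons else "fail",
                "reasons": reasons,
            }
        )
    return report
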