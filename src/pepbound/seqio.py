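"""Read processing and count-table I/O for peptide-display selection data.

Merged amplicon reads are scanned for the variable region between two
constant anchor sequences, quality-filtered, checked against the library
design (codon scheme, fixed residues) and translated.  The resulting
peptide multisets for the input and bound libraries of each selection
round are tabulated into :class:`CountTable` objects, the central data
container consumed by model fitting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio import SeqIO

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


@dataclass
class MergedRead:
    """A merged (single-ended) amplicon read with per-base PHRED scores."""

    dna: str
    quality: list[int]

    def __post_init__(self) -> None:
        if len(self.dna) != len(self.quality):
            raise ValueError("dna and quality must have equal length")
        bad = set(self.dna) - set("ACGTN")
        if bad:
            raise ValueError(f"unexpected nucleotides: {sorted(bad)}")


@dataclass
class LibraryDesign:
    """Description of a degenerate display library.

    The variable region of ``var_len_nt`` bases (``var_len_aa`` codons) sits
    between two constant nucleotide anchors in the amplicon and, at the
    protein level, between two constant flanking peptides that are part of
    the display scaffold.  ``fixed_positions`` maps 0-based amino-acid
    positions to required residues (e.g. ``{5: "Y"}`` for a library with a
    fixed central tyrosine); an empty map describes a fully random library.
    """

    var_len_aa: int = 11
    fixed_positions: dict[int, str] = field(default_factory=dict)
    left_flank_aa: str = "GQSGQ"
    right_flank_aa: str = "GGQSG"
    left_anchor_nt: str = "GTAGCTGGCCAGTCTGGCCAG"
    right_anchor_nt: str = "GGAGGGCAGTCTGGGCAGTC"
    codon_model: str = "NNS"

    @property
    def var_len_nt(self) -> int:
        return 3 * self.var_len_aa

    def __post_init__(self) -> None:
        for pos, res in self.fixed_positions.items():
            if not 0 <= pos < self.var_len_aa:
                raise ValueError(f"fixed position {pos} outside variable region")
            if res not in AA_INDEX:
                raise ValueError(f"fixed residue {res!r} not a canonical amino acid")

    @classmethod
    def from_yaml(cls, path) -> "LibraryDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "fixed_positions" in raw and raw["fixed_positions"]:
            raw["fixed_positions"] = {int(k): v for k, v in raw["fixed_positions"].items()}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "var_len_aa": self.var_len_aa,
            "fixed_positions": dict(self.fixed_positions),
            "left_flank_aa": self.left_flank_aa,
            "right_flank_aa": self.right_flank_aa,
            "left_anchor_nt": self.left_anchor_nt,
            "right_anchor_nt": self.right_anchor_nt,
            "codon_model": self.codon_model,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class CountTable:
    """Paired input/bound read counts over observed peptides for one round."""

    round_label: str
    sequences: list[str]
    input_counts: np.ndarray
    bound_counts: np.ndarray

    def __post_init__(self) -> None:
        self.input_counts = np.asarray(self.input_counts, dtype=np.int64)
        self.bound_counts = np.asarray(self.bound_counts, dtype=np.int64)
        n = len(self.sequences)
        if self.input_counts.shape != (n,) or self.bound_counts.shape != (n,):
            raise ValueError("count arrays must match number of sequences")
        if (self.input_counts < 0).any() or (self.bound_counts < 0).any():
            raise ValueError("counts must be non-negative")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("all sequences must share one length")

    @property
    def seq_len(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def total_reads(self) -> int:
        """Total reads k_c: the sum of both the input and the bound column."""
        return int(self.input_counts.sum() + self.bound_counts.sum())

    def drop_empty_rows(self) -> "CountTable":
        keep = (self.input_counts + self.bound_counts) >= 1
        return CountTable(
            self.round_label,
            [s for s, k in zip(self.sequences, keep) if k],
            self.input_counts[keep],
            self.bound_counts[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": self.sequences,
                "input": self.input_counts,
                "bound": self.bound_counts,
            }
        )


def encode_peptides(sequences: list[str]) -> np.ndarray:
    """Encode peptides as an (n, L) int8 array of alphabet indices."""
    if not sequences:
        return np.zeros((0, 0), dtype=np.int8)
    arr = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(sequences), len(sequences[0]))
    lut = np.full(128, -1, dtype=np.int8)
    for aa, i in AA_INDEX.items():
        lut[ord(aa)] = i
    enc = lut[arr]
    if (enc < 0).any():
        raise ValueError("sequence contains a non-canonical residue")
    return enc


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_variable_region(
    read: MergedRead, design: LibraryDesign, max_mismatch: int = 5
) -> tuple[str, list[int]] | None:
    """Locate the variable region between the two anchors.

    Every placement of (left anchor, variable region, right anchor) within
    the read is scored by the combined Hamming mismatch count of the two
    anchors; the best placement wins (leftmost on ties).  Returns the
    variable-region nucleotides and their PHRED scores, or ``None`` if no
    placement has at most ``max_mismatch`` combined mismatches.
    """
    la, ra = design.left_anchor_nt, design.right_anchor_nt
    if not la or not ra:
        raise ValueError("anchors must be non-empty")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    span = len(la) + design.var_len_nt + len(ra)
    if len(read.dna) < span:
        return None
    best_mm, best_start = None, None
    for start in range(len(read.dna) - span + 1):
        mm = _hamming(read.dna[start : start + len(la)], la)
        if best_mm is not None and mm > best_mm:
            continue
        rstart = start + len(la) + design.var_len_nt
        mm += _hamming(read.dna[rstart : rstart + len(ra)], ra)
        if best_mm is None or mm < best_mm:
            best_mm, best_start = mm, start
    if best_mm is None or best_mm > max_mismatch:
        return None
    lo = best_start + len(la)
    hi = lo + design.var_len_nt
    return read.dna[lo:hi], read.quality[lo:hi]


def filter_translate(
    region_nt: str,
    region_quality: list[int],
    design: LibraryDesign,
    min_phred: int = 20,
) -> str | None:
    """Quality-filter and translate a cropped variable region.

    Returns ``None`` (read discarded) if any base falls below ``min_phred``,
    if any codon violates the design's codon model, if translation yields a
    stop codon, or if a design-fixed position carries the wrong residue.
    """
    if len(region_nt) != design.var_len_nt:
        raise ValueError("region length does not match design")
    if "N" in region_nt:
        return None
    if any(q < min_phred for q in region_quality):
        return None
    if design.codon_model.upper() == "NNS":
        # S = strong: third codon base must be G or C
        if any(region_nt[i] not in "GC" for i in range(2, len(region_nt), 3)):
            return None
    peptide = str(Seq(region_nt).translate())
    if "*" in peptide or any(aa not in AA_INDEX for aa in peptide):
        return None
    for pos, res in design.fixed_positions.items():
        if peptide[pos] != res:
            return None
    return peptide


def read_fastq(path) -> list[MergedRead]:
    """Load merged reads from a Sanger-encoded (PHRED+33) FASTQ file."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(MergedRead(str(rec.seq).upper(), rec.letter_annotations["phred_quality"]))
    return reads


def process_reads(
    reads: list[MergedRead],
    design: LibraryDesign,
    max_mismatch: int = 5,
    min_phred: int = 20,
) -> tuple[list[str], dict[str, int]]:
    """Run the full read-processing chain, returning surviving peptides.

    The second return value tallies how many reads fell at each stage
    (``no_anchor``, ``filtered``, ``passed``).
    """
    peptides: list[str] = []
    stats = {"total": len(reads), "no_anchor": 0, "filtered": 0, "passed": 0}
    for read in reads:
        hit = extract_variable_region(read, design, max_mismatch)
        if hit is None:
            stats["no_anchor"] += 1
            continue
        pep = filter_translate(hit[0], hit[1], design, min_phred)
        if pep is None:
            stats["filtered"] += 1
            continue
        stats["passed"] += 1
        peptides.append(pep)
    return peptides, stats


def build_count_table(
    input_peptides: list[str], bound_peptides: list[str], round_label: str
) -> CountTable:
    """Tabulate peptide multisets into a per-round count table.

    One row per distinct peptide seen in either library; counts are the
    multiset multiplicities, so the table conserves reads exactly.
    """
    lengths = {len(p) for p in input_peptides} | {len(p) for p in bound_peptides}
    if len(lengths) > 1:
        raise ValueError("mixed peptide lengths")
    seqs = sorted(set(input_peptides) | set(bound_peptides))
    idx = {s: i for i, s in enumerate(seqs)}
    inp = np.zeros(len(seqs), dtype=np.int64)
    bnd = np.zeros(len(seqs), dtype=np.int64)
    for p in input_peptides:
        inp[idx[p]] += 1
    for p in bound_peptides:
        bnd[idx[p]] += 1
    return CountTable(round_label, seqs, inp, bnd)


def subsample_table(table: CountTable, depth: int, seed: int) -> CountTable:
    """Down-sample both columns to ``depth`` reads each, without replacement.

    Each column is treated as an urn of reads and sampled by a multivariate
    hypergeometric draw, so expectations scale linearly with depth and full
    depth is the identity.
    """
    rng = np.random.default_rng(seed)
    cols = []
    for counts in (table.input_counts, table.bound_counts):
        total = int(counts.sum())
        if depth > total:
            raise ValueError(f"depth {depth} exceeds column total {total}")
        if depth == total:
            cols.append(counts.copy())
        else:
            cols.append(
                rng.multivariate_hypergeometric(counts, depth, method="marginals")
            )
    return CountTable(table.round_label, list(table.sequences), cols[0], cols[1])


def write_count_table(table: CountTable, path) -> None:
    """Serialize a count table as 3-column TSV with the round label in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# round_label: {table.round_label}\n")
        fh.write("sequence\tinput\tbound\n")
        for s, i, b in zip(table.sequences, table.input_counts, table.bound_counts):
            fh.write(f"{s}\t{i}\t{b}\n")


def read_count_table(path) -> CountTable:
    round_label = ""
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            if "round_label:" in line:
                round_label = line.split("round_label:", 1)[1].strip()
        else:
            break
    df = pd.read_csv(
        io.StringIO("\n".join(lines[body_start:])),
        sep="\t",
        dtype={"sequence": str, "input": np.int64, "bound": np.int64},
    )
    return CountTable(
        round_label,
        df["sequence"].tolist(),
        df["input"].to_numpy(),
        df["bound"].to_numpy(),
    )
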