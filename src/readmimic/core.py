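"""Nucleotide-content-matched NGS read simulation.

Many sequencing protocols produce reads with a characteristic positional
nucleotide composition: XR-seq reads are thymine-enriched near the 3' end,
damage-seq reads are pyrimidine-enriched around the lesion site, and
immunoprecipitation or ligation steps can imprint their own biases. Because
genomes are themselves heterogeneous in sequence content, the genome-wide
distribution of such reads confounds the biological signal with plain
sequence-composition preference. This module generates synthetic reads whose
positional nucleotide (or k-mer) profile mimics that of a set of input reads
while their genomic placement is random, so that the simulated reads serve as
a sequence-content null for fold-change normalization downstream.

The method, in the order it runs:

1. Input reads (FASTA/FASTQ) are filtered: any read containing an ambiguous
   base (N) is discarded.
2. The positional k-mer frequency profile of the retained reads is computed,
   per read length (the *target* profile).
3. For each input read, a fixed number of candidate subsequences of the same
   length (default 50) are drawn uniformly from the reference genome
   (optionally restricted to BED regions, optionally from input DNA
   sequencing reads instead), scored position-by-position against the current
   *working* profile, and one candidate is selected by a score-weighted draw.
4. After every 10% of reads, the working profile is nudged toward the target:
   half of the difference between the profile of reads simulated so far and
   the target profile is subtracted from the working profile, so the output
   profile converges to the input profile regardless of read order.

Simulated reads match the input in count and per-length distribution, can
copy the input quality strings verbatim, and can be exported as FASTA, FASTQ
or BED (genomic coordinates, reference mode only).

Sequencing errors, genetic variation, quality-score models and paired-end
layouts are deliberately out of scope: the only quantity being modelled is
positional sequence content.
"""

from __future__ import annotations

import gzip
import io
import logging
import time
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy import stats

__all__ = [
    "ReadRecord",
    "ReferenceGenome",
    "GenomicInterval",
    "NucleotideProfile",
    "ProfileComparison",
    "SimulationConfig",
    "SimulatedRead",
    "RunSummary",
    "ReadMimicError",
    "ParseError",
    "ValidationError",
    "ProfileError",
    "SimulationError",
    "UnsupportedOutputError",
    "read_sequences",
    "detect_format",
    "load_reference",
    "load_regions",
    "write_reads",
    "compute_profile",
    "adjust_profile",
    "profile_distance",
    "hotelling_t2",
    "dump_profile",
    "load_profile",
    "filter_ambiguous",
    "sample_candidate",
    "sample_candidate_from_reads",
    "score_read",
    "select_candidate",
    "simulate",
    "make_fixtures",
]

logger = logging.getLogger("readmimic")
logger.addHandler(logging.NullHandler())

# ---------------------------------------------------------------------------
# Constants and errors
# ---------------------------------------------------------------------------

#: Pseudocount added to positional frequencies before taking logarithms, so
#: candidates carrying a k-mer never observed in the input remain scoreable.
PSEUDOCOUNT = 1e-6

#: Default number of genome subsequences scored per input read ("sens").
DEFAULT_CANDIDATE_COUNT = 50

#: Abort threshold for consecutive rejected candidates (N-rich references).
MAX_CONSECUTIVE_REJECTIONS = 10_000

_ROW_SUM_TOL = 1e-9


class ReadMimicError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(ReadMimicError):
    """A FASTA/FASTQ record could not be parsed."""


class ValidationError(ReadMimicError):
    """An interval, configuration or argument failed validation."""


class ProfileError(ReadMimicError):
    """A profile operation received incompatible or degenerate input."""


class SimulationError(ReadMimicError):
    """Candidate sampling or read generation failed."""


class UnsupportedOutputError(ReadMimicError):
    """The requested output format is not available for this run mode."""


# ---------------------------------------------------------------------------
# Sequence encoding helpers
# ---------------------------------------------------------------------------

# A=0 C=1 G=2 T=3, anything else (including IUPAC ambiguity codes) = 4.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _encode(sequence: str) -> np.ndarray:
    """Encode a sequence string as uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _kmer_index_matrix(codes: np.ndarray, k: int) -> np.ndarray:
    """Map base codes to k-mer column indices (lexicographic over A<C<G<T).

    ``codes`` has shape (..., L) with values in 0..3; the result has shape
    (..., L-k+1) with values in 0..4**k-1.
    """
    if k == 1:
        return codes.astype(np.intp)
    win = np.lib.stride_tricks.sliding_window_view(codes, k, axis=-1)
    powers = 4 ** np.arange(k - 1, -1, -1)
    return (win.astype(np.intp) * powers).sum(axis=-1)


def kmer_name(index: int, k: int) -> str:
    """Lexicographic k-mer string for a column index (inverse of encoding)."""
    out = []
    for _ in range(k):
        out.append("ACGT"[index % 4])
        index //= 4
    return "".join(reversed(out))


# ---------------------------------------------------------------------------
# Domain types: reads, genome, intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadRecord:
    """One input or output read.

    ``quality`` is the raw FASTQ quality string (Phred+33 by convention) and
    is treated as opaque: it is never decoded, only carried along.
    """

    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"read {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValidationError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class ReferenceGenome:
    """Named chromosome sequences with a cumulative-length index.

    The index supports drawing start positions uniformly over all valid
    positions genome-wide without ever crossing a chromosome boundary.
    Sequences are uppercased on ingest; soft-masked bases are treated as
    normal bases.
    """

    def __init__(self, chromosomes: Dict[str, str]):
        if not chromosomes:
            raise ValidationError("reference genome has no sequences")
        for name, seq in chromosomes.items():
            if not seq:
                raise ValidationError(f"chromosome {name!r} has zero length")
        self.chromosomes: Dict[str, str] = {
            name: seq.upper() for name, seq in chromosomes.items()
        }
        self.names: List[str] = list(self.chromosomes)
        self.lengths: Dict[str, int] = {
            name: len(seq) for name, seq in self.chromosomes.items()
        }
        lengths = np.array([self.lengths[n] for n in self.names], dtype=np.int64)
        #: running totals per chromosome, strictly increasing
        self.cumulative_offsets: np.ndarray = np.cumsum(lengths)
        self.total_length: int = int(self.cumulative_offsets[-1])
        self._codes: Optional[np.ndarray] = None

    @property
    def codes(self) -> np.ndarray:
        """All chromosomes concatenated as uint8 base codes (built lazily)."""
        if self._codes is None:
            self._codes = _encode("".join(self.chromosomes[n] for n in self.names))
        return self._codes

    def offset_of(self, chrom: str) -> int:
        """Start offset of a chromosome in the concatenated coordinate."""
        i = self.names.index(chrom)
        return 0 if i == 0 else int(self.cumulative_offsets[i - 1])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chromosomes[chrom][start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes


@dataclass(frozen=True)
class GenomicInterval:
    """BED-semantics interval: 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Sequence I/O (FASTA, FASTQ, BED)
# ---------------------------------------------------------------------------


def _open_text(path: Union[str, Path], mode: str = "rt") -> io.TextIOBase:
    # gzip transparency is a convenience, not a contract
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def detect_format(path: Union[str, Path]) -> str:
    """Sniff ``fasta`` vs ``fastq`` from the first non-blank character."""
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                first = line[0]
                if first == ">":
                    return "fasta"
                if first == "@":
                    return "fastq"
                raise ParseError(
                    f"{path}: cannot detect format (first record starts with "
                    f"{first!r}, expected '>' or '@')"
                )
    raise ParseError(f"{path}: empty file")


def read_sequences(
    path: Union[str, Path], format: Optional[str] = None
) -> List[ReadRecord]:
    """Read all records from a FASTA or FASTQ file.

    Sequences are uppercased; FASTQ quality strings are carried verbatim.
    ``format`` is sniffed from the file content when not given. Malformed
    records raise :class:`ParseError` naming the record index.
    """
    fmt = format or detect_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValidationError(f"unknown read format {fmt!r}")
    records: List[ReadRecord] = []
    with _open_text(path) as fh:
        if fmt == "fasta":
            iterator: Iterable = SimpleFastaParser(fh)
        else:
            iterator = FastqGeneralIterator(fh)
        it = iter(iterator)
        index = 0
        while True:
            try:
                item = next(it)
            except StopIteration:
                break
            except ValueError as exc:  # Biopython's malformed-record signal
                raise ParseError(f"{path}: record {index}: {exc}") from exc
            if fmt == "fasta":
                title, seq = item
                quality = None
            else:
                title, seq, quality = item
            try:
                records.append(
                    ReadRecord(
                        id=title.split(None, 1)[0] if title else f"record_{index}",
                        sequence=seq.upper(),
                        quality=quality,
                    )
                )
            except ValidationError as exc:
                raise ParseError(f"{path}: record {index}: {exc}") from exc
            index += 1
    return records


def load_reference(path: Union[str, Path]) -> ReferenceGenome:
    """Load a reference genome from FASTA (multi-line records supported)."""
    chromosomes: Dict[str, str] = {}
    with _open_text(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split(None, 1)[0]
            if not seq:
                raise ValidationError(f"{path}: chromosome {name!r} is empty")
            chromosomes[name] = seq.upper()
    if not chromosomes:
        raise ValidationError(f"{path}: no sequences found")
    return ReferenceGenome(chromosomes)


def load_regions(
    path: Union[str, Path], genome: ReferenceGenome
) -> List[GenomicInterval]:
    """Load a BED region-restriction file, validated against the genome.

    BED is 0-based half-open. A strand column, if present, is ignored here:
    within a region both strands may be sampled.
    """
    intervals: List[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if chrom not in genome:
                raise ValidationError(
                    f"{path}: line {lineno}: unknown chromosome {chrom!r}"
                )
            if not (0 <= start < end <= genome.lengths[chrom]):
                raise ValidationError(
                    f"{path}: line {lineno}: interval {start}-{end} out of "
                    f"bounds for {chrom} (length {genome.lengths[chrom]})"
                )
            intervals.append(GenomicInterval(chrom, start, end))
    return intervals


def write_reads(
    reads: Sequence["SimulatedRead"],
    path: Union[str, Path],
    format: str,
) -> int:
    """Write simulated reads as FASTA, FASTQ or BED; return the count written.

    BED output requires genomic coordinates and is therefore only available
    in reference mode; FASTQ output requires quality strings on every read.
    """
    if format not in ("fasta", "fastq", "bed"):
        raise ValidationError(f"unknown output format {format!r}")
    if format == "bed" and any(r.interval is None for r in reads):
        raise UnsupportedOutputError(
            "BED output requires genomic coordinates; reads simulated from "
            "input sequencing have none"
        )
    if format == "fastq" and any(r.quality is None for r in reads):
        raise UnsupportedOutputError(
            "FASTQ output requires quality strings; input was FASTA "
            "(use constant-quality mode or FASTA output)"
        )
    n = 0
    with _open_text(path, "wt") as fh:
        for read in reads:
            if format == "fasta":
                fh.write(f">{read.id}\n{read.sequence}\n")
            elif format == "fastq":
                fh.write(f"@{read.id}\n{read.sequence}\n+\n{read.quality}\n")
            else:
                iv = read.interval
                assert iv is not None
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{read.id}\t0\t{iv.strand}\n"
                )
            n += 1
    return n


def _write_fasta_wrapped(
    sequences: Dict[str, str], path: Union[str, Path], width: int = 70
) -> None:
    """Write reference-style FASTA wrapped at ``width`` columns."""
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Positional nucleotide / k-mer profiles
# ---------------------------------------------------------------------------


@dataclass
class NucleotideProfile:
    """Per-read-length positional k-mer frequency matrices.

    For each read length L present in the source reads, ``freqs[L]`` is an
    (L - k + 1) x 4**k matrix whose row p gives the frequency of each k-mer
    (columns in lexicographic order over A<C<G<T) starting at position p
    among reads of length L. Positional frequencies are only well defined
    within one length, so lengths are kept independent throughout.
    """

    k: int
    freqs: Dict[int, np.ndarray]
    n_reads: Dict[int, int]
    counts: Optional[Dict[int, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ProfileError(f"k must be >= 1, got {self.k}")
        for L, mat in self.freqs.items():
            if mat.shape != (L - self.k + 1, 4**self.k):
                raise ProfileError(
                    f"length {L}: expected frequency matrix of shape "
                    f"({L - self.k + 1}, {4 ** self.k}), got {mat.shape}"
                )
            if np.any(mat < -_ROW_SUM_TOL) or np.any(mat > 1 + _ROW_SUM_TOL):
                raise ProfileError(f"length {L}: frequencies outside [0, 1]")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
                raise ProfileError(f"length {L}: rows do not sum to 1")

    def lengths(self) -> List[int]:
        return sorted(self.freqs)

    def dominant_length(self) -> int:
        """The most populous read length (ties broken toward the longer)."""
        return max(self.n_reads, key=lambda L: (self.n_reads[L], L))

    def copy(self) -> "NucleotideProfile":
        return NucleotideProfile(
            k=self.k,
            freqs={L: m.copy() for L, m in self.freqs.items()},
            n_reads=dict(self.n_reads),
            counts=None
            if self.counts is None
            else {L: m.copy() for L, m in self.counts.items()},
        )


@dataclass(frozen=True)
class ProfileComparison:
    """Two-sample Hotelling's T² comparison of two positional profiles."""

    t2: float
    f_stat: float
    df1: int
    df2: int
    p_value: float


def compute_profile(reads: Sequence[ReadRecord], k: int = 1) -> NucleotideProfile:
    """Compute the positional k-mer frequency profile of a read set.

    Reads must be free of ambiguous bases (filter with
    :func:`filter_ambiguous` first) and at least k long. Profiles for
    different read lengths are independent; the result is invariant to the
    order of the reads.
    """
    if k < 1:
        raise ProfileError(f"k must be >= 1, got {k}")
    if not reads:
        raise ProfileError("cannot compute a profile from an empty read set")
    by_length: Dict[int, List[str]] = defaultdict(list)
    for read in reads:
        if len(read.sequence) < k:
            raise ProfileError(
                f"read {read.id!r} (length {len(read.sequence)}) is shorter "
                f"than k={k}"
            )
        by_length[len(read.sequence)].append(read.sequence)
    n_cols = 4**k
    freqs: Dict[int, np.ndarray] = {}
    counts: Dict[int, np.ndarray] = {}
    n_reads: Dict[int, int] = {}
    for L, seqs in by_length.items():
        codes = _encode("".join(seqs)).reshape(len(seqs), L)
        if np.any(codes > 3):
            bad = int(np.argwhere(codes > 3)[0, 0])
            raise ProfileError(
                f"read {seqs[bad][:20]!r}...: contains ambiguous bases; "
                "filter with filter_ambiguous first"
            )
        km = _kmer_index_matrix(codes, k)
        n_pos = L - k + 1
        cnt = np.zeros((n_pos, n_cols), dtype=np.int64)
        for p in range(n_pos):
            cnt[p] = np.bincount(km[:, p], minlength=n_cols)
        counts[L] = cnt
        freqs[L] = cnt / len(seqs)
        n_reads[L] = len(seqs)
    return NucleotideProfile(k=k, freqs=freqs, n_reads=n_reads, counts=counts)


def adjust_profile(
    working: NucleotideProfile,
    simulated_so_far: NucleotideProfile,
    target: NucleotideProfile,
    fraction: float = 0.5,
) -> NucleotideProfile:
    """Move the working profile toward the target by the convergence rule.

    For every length, position and k-mer the raw update is
    ``working - fraction * (simulated_so_far - target)``; negative entries
    are clamped to zero and each positional row renormalized to sum to 1.
    Lengths not yet present in ``simulated_so_far`` pass through unchanged.
    The default fraction of 0.5 subtracts half of the difference between the
    simulated-so-far and observed profiles.
    """
    if not (0 < fraction <= 1):
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    if not (working.k == simulated_so_far.k == target.k):
        raise ProfileError(
            f"mismatched k between profiles: working k={working.k}, "
            f"simulated k={simulated_so_far.k}, target k={target.k}"
        )
    new_freqs: Dict[int, np.ndarray] = {}
    for L in working.lengths():
        mat = working.freqs[L]
        if L in simulated_so_far.freqs and L in target.freqs:
            raw = mat - fraction * (simulated_so_far.freqs[L] - target.freqs[L])
            np.clip(raw, 0.0, None, out=raw)
            # row sums stay positive: the raw rows sum to exactly 1 before
            # clamping, so at least one entry per row is positive
            raw /= raw.sum(axis=1, keepdims=True)
            new_freqs[L] = raw
        else:
            new_freqs[L] = mat.copy()
    return NucleotideProfile(
        k=working.k, freqs=new_freqs, n_reads=dict(working.n_reads)
    )


def profile_distance(a: NucleotideProfile, b: NucleotideProfile) -> float:
    """Maximum absolute frequency difference over all shared lengths."""
    if a.k != b.k:
        raise ProfileError(f"mismatched k: {a.k} vs {b.k}")
    shared = set(a.freqs) & set(b.freqs)
    if not shared:
        raise ProfileError("profiles share no read lengths")
    return max(float(np.abs(a.freqs[L] - b.freqs[L]).max()) for L in shared)


def hotelling_t2(a: NucleotideProfile, b: NucleotideProfile) -> ProfileComparison:
    """Two-sample Hotelling's T² between two single-nucleotide profiles.

    Each observation is the (A, C, G) frequency vector of one position of the
    dominant shared read length; T is dropped because the four frequencies
    sum to 1 and would make the covariance singular. The p-value comes from
    the standard F approximation with d = 3 dimensions:
    ``T² * (n1 + n2 - d - 1) / (d * (n1 + n2 - 2)) ~ F(d, n1 + n2 - d - 1)``.

    The statistic is symmetric in its arguments.
    """
    if a.k != 1 or b.k != 1:
        raise ProfileError("hotelling_t2 requires single-nucleotide profiles (k=1)")
    shared = set(a.freqs) & set(b.freqs)
    if not shared:
        raise ProfileError("profiles share no read lengths")
    L = max(
        shared,
        key=lambda l: (a.n_reads.get(l, 0) + b.n_reads.get(l, 0), l),
    )
    X = a.freqs[L][:, :3]
    Y = b.freqs[L][:, :3]
    n1, n2 = X.shape[0], Y.shape[0]
    d = 3
    if n1 < 5 or n2 < 5:
        raise ProfileError(
            f"need >=5 positions per profile for Hotelling's T2 "
            f"(got {n1} and {n2} at length {L})"
        )
    if n1 + n2 - d - 1 < 1:
        raise ProfileError("too few positions for the F approximation")
    mean_diff = X.mean(axis=0) - Y.mean(axis=0)
    s_pooled = (
        (n1 - 1) * np.cov(X, rowvar=False) + (n2 - 1) * np.cov(Y, rowvar=False)
    ) / (n1 + n2 - 2)
    try:
        solved = np.linalg.solve(s_pooled, mean_diff)
    except np.linalg.LinAlgError as exc:
        raise ProfileError(
            "singular pooled covariance (positional frequencies may be "
            "constant); inspect the profiles before comparing"
        ) from exc
    t2 = float(n1 * n2 / (n1 + n2) * mean_diff @ solved)
    df1, df2 = d, n1 + n2 - d - 1
    f_stat = t2 * df2 / (d * (n1 + n2 - 2))
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return ProfileComparison(
        t2=t2, f_stat=float(f_stat), df1=df1, df2=df2, p_value=p_value
    )


def dump_profile(profile: NucleotideProfile, path: Union[str, Path]) -> None:
    """Write a profile as plain TSV (length, position, kmer, frequency).

    Intended for inspection and plotting, not a stability contract.
    """
    with _open_text(path, "wt") as fh:
        fh.write(f"#k\t{profile.k}\n")
        for L in profile.lengths():
            fh.write(f"#n_reads\t{L}\t{profile.n_reads.get(L, 0)}\n")
        fh.write("length\tposition\tkmer\tfrequency\n")
        for L in profile.lengths():
            mat = profile.freqs[L]
            for p in range(mat.shape[0]):
                for m in range(mat.shape[1]):
                    fh.write(
                        f"{L}\t{p}\t{kmer_name(m, profile.k)}\t"
                        f"{mat[p, m]:.10g}\n"
                    )


def load_profile(path: Union[str, Path]) -> NucleotideProfile:
    """Read a profile dumped by :func:`dump_profile`."""
    k = 1
    n_reads: Dict[int, int] = {}
    rows: List[Tuple[int, int, str, float]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#k\t"):
                k = int(line.split("\t")[1])
            elif line.startswith("#n_reads\t"):
                _, L, n = line.split("\t")
                n_reads[int(L)] = int(n)
            elif line and not line.startswith(("#", "length\t")):
                Ls, ps, mer, f = line.split("\t")
                rows.append((int(Ls), int(ps), mer, float(f)))
    freqs: Dict[int, np.ndarray] = {}
    for L, p, mer, f in rows:
        if L not in freqs:
            freqs[L] = np.zeros((L - k + 1, 4**k))
        col = _kmer_index_matrix(_encode(mer), k)[0]
        freqs[L][p, col] = f
    return NucleotideProfile(
        k=k, freqs=freqs, n_reads={L: n_reads.get(L, 0) for L in freqs}
    )


# ---------------------------------------------------------------------------
# Candidate sampling
# ---------------------------------------------------------------------------


class _GenomeSampler:
    """Uniform candidate sampling over a genome or a region restriction.

    Genome-wide sampling is region sampling over full-chromosome intervals:
    one code path, identical uniform-over-valid-starts semantics. Candidates
    never cross a region (hence chromosome) boundary; strand is drawn with
    probability 1/2 each and minus-strand candidates are reverse-complemented.
    Candidates containing non-ACGT bases are rejected and redrawn.
    """

    def __init__(
        self,
        genome: ReferenceGenome,
        regions: Optional[Sequence[GenomicInterval]] = None,
    ):
        self.genome = genome
        if regions is None:
            regs = [
                GenomicInterval(name, 0, genome.lengths[name])
                for name in genome.names
            ]
        else:
            if not regions:
                raise ValidationError("empty region list")
            for iv in regions:
                if iv.chrom not in genome:
                    raise ValidationError(f"unknown chromosome {iv.chrom!r}")
                if iv.end > genome.lengths[iv.chrom]:
                    raise ValidationError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {genome.lengths[iv.chrom]}"
                    )
            regs = list(regions)
        self._chroms = [iv.chrom for iv in regs]
        self._starts = np.array([iv.start for iv in regs], dtype=np.int64)
        self._lens = np.array([len(iv) for iv in regs], dtype=np.int64)
        self._abs = np.array(
            [genome.offset_of(iv.chrom) + iv.start for iv in regs], dtype=np.int64
        )
        self._cum_cache: Dict[int, Tuple[np.ndarray, int]] = {}

    def _valid_cumsum(self, length: int) -> Tuple[np.ndarray, int]:
        cached = self._cum_cache.get(length)
        if cached is None:
            valid = np.maximum(self._lens - length + 1, 0)
            cum = np.cumsum(valid)
            total = int(cum[-1])
            cached = (cum, total)
            self._cum_cache[length] = cached
        return cached

    def draw(
        self, length: int, count: int, rng: np.random.Generator
    ) -> Tuple[np.ndarray, List[GenomicInterval]]:
        """Draw ``count`` valid candidates of ``length``; return codes + intervals."""
        if length < 1:
            raise ValidationError(f"candidate length must be >= 1, got {length}")
        cum, total = self._valid_cumsum(length)
        if total == 0:
            raise SimulationError(
                f"no region or chromosome can hold a read of length {length}"
            )
        conc = self.genome.codes
        offsets = np.arange(length)
        codes = np.empty((count, length), dtype=np.uint8)
        reg_idx = np.empty(count, dtype=np.int64)
        reg_off = np.empty(count, dtype=np.int64)
        minus = np.empty(count, dtype=bool)
        pending = np.arange(count)
        rounds = 0
        while pending.size:
            g = rng.integers(0, total, size=pending.size)
            r = np.searchsorted(cum, g, side="right")
            off = g - np.where(r > 0, cum[r - 1], 0)
            win = conc[(self._abs[r] + off)[:, None] + offsets]
            strand_minus = rng.random(pending.size) < 0.5
            ok = ~(win > 3).any(axis=1)
            sel = pending[ok]
            codes[sel] = win[ok]
            reg_idx[sel] = r[ok]
            reg_off[sel] = off[ok]
            minus[sel] = strand_minus[ok]
            pending = pending[~ok]
            rounds += 1
            if pending.size and rounds > MAX_CONSECUTIVE_REJECTIONS:
                raise SimulationError(
                    f"more than {MAX_CONSECUTIVE_REJECTIONS} consecutive "
                    "candidate rejections; the reference may be N-rich in "
                    "the sampled regions"
                )
        # reverse-complement minus-strand candidates (codes are all <= 3 here)
        if minus.any():
            codes[minus] = (3 - codes[minus])[:, ::-1]
        intervals = [
            GenomicInterval(
                self._chroms[ri],
                int(self._starts[ri] + ro),
                int(self._starts[ri] + ro + length),
                "-" if m else "+",
            )
            for ri, ro, m in zip(reg_idx, reg_off, minus)
        ]
        return codes, intervals


class _ReadsSampler:
    """Candidate sampling from input DNA-sequencing reads.

    A source read long enough to hold the candidate is chosen with
    probability proportional to its number of valid substring start
    positions, then the start offset is uniform within it. This makes every
    substring of every sufficiently long source read equally likely.
    """

    def __init__(self, source_reads: Sequence[ReadRecord]):
        if not source_reads:
            raise ValidationError("no input-sequencing reads supplied")
        self._codes = [_encode(r.sequence) for r in source_reads]
        self._lens = np.array([len(r.sequence) for r in source_reads], dtype=np.int64)
        self._cum_cache: Dict[int, Tuple[np.ndarray, int]] = {}

    def _valid_cumsum(self, length: int) -> Tuple[np.ndarray, int]:
        cached = self._cum_cache.get(length)
        if cached is None:
            valid = np.maximum(self._lens - length + 1, 0)
            cum = np.cumsum(valid)
            cached = (cum, int(cum[-1]))
            self._cum_cache[length] = cached
        return cached

    def draw(
        self, length: int, count: int, rng: np.random.Generator
    ) -> Tuple[np.ndarray, None]:
        if length < 1:
            raise ValidationError(f"candidate length must be >= 1, got {length}")
        cum, total = self._valid_cumsum(length)
        if total == 0:
            raise SimulationError(
                f"no input-sequencing read is long enough for length {length}"
            )
        codes = np.empty((count, length), dtype=np.uint8)
        pending = list(range(count))
        rounds = 0
        while pending:
            g = rng.integers(0, total, size=len(pending))
            r = np.searchsorted(cum, g, side="right")
            off = g - np.where(r > 0, cum[r - 1], 0)
            still = []
            for slot, ri, oi in zip(pending, r, off):
                win = self._codes[ri][oi : oi + length]
                if (win > 3).any():
                    still.append(slot)
                else:
                    codes[slot] = win
            pending = still
            rounds += 1
            if pending and rounds > MAX_CONSECUTIVE_REJECTIONS:
                raise SimulationError(
                    f"more than {MAX_CONSECUTIVE_REJECTIONS} consecutive "
                    "candidate rejections from input-sequencing reads"
                )
        return codes, None


def sample_candidate(
    genome: ReferenceGenome,
    regions: Optional[Sequence[GenomicInterval]],
    length: int,
    rng: np.random.Generator,
) -> Tuple[str, GenomicInterval]:
    """Draw one valid candidate subsequence from the reference genome.

    The start position is uniform over all valid start positions (within the
    regions if given), the strand is a fair coin, and minus-strand candidates
    are reverse-complemented. The returned interval carries forward-strand
    coordinates plus the strand. Candidates containing non-ACGT bases are
    redrawn internally.
    """
    sampler = _GenomeSampler(genome, regions)
    codes, intervals = sampler.draw(length, 1, rng)
    return _decode(codes[0]), intervals[0]


def sample_candidate_from_reads(
    source_reads: Sequence[ReadRecord],
    length: int,
    rng: np.random.Generator,
) -> str:
    """Draw one candidate substring from input DNA-sequencing reads."""
    sampler = _ReadsSampler(source_reads)
    codes, _ = sampler.draw(length, 1, rng)
    return _decode(codes[0])


# ---------------------------------------------------------------------------
# Scoring and selection
# ---------------------------------------------------------------------------


def _log_frequencies(profile: NucleotideProfile, length: int) -> np.ndarray:
    if length not in profile.freqs:
        raise ProfileError(f"profile has no entry for read length {length}")
    return np.log(profile.freqs[length] + PSEUDOCOUNT)


def _score_batch(km: np.ndarray, logfreq: np.ndarray) -> np.ndarray:
    """Log-scores for a batch of candidates given positional log-frequencies.

    ``km``: (count, P) k-mer indices; ``logfreq``: (P, 4**k).
    """
    positions = np.arange(km.shape[1])
    return logfreq[positions[None, :], km].sum(axis=1)


def score_read(sequence: str, profile: NucleotideProfile) -> float:
    """Positional log-likelihood of a sequence under a profile.

    The score is the sum over k-mer positions of
    ``log(frequency + PSEUDOCOUNT)``; higher means more profile-like.
    """
    L = len(sequence)
    codes = _encode(sequence)
    if np.any(codes > 3):
        raise ValidationError(f"sequence contains non-ACGT bases: {sequence[:30]!r}")
    if L < profile.k:
        raise ProfileError(f"sequence length {L} is shorter than k={profile.k}")
    logfreq = _log_frequencies(profile, L)
    km = _kmer_index_matrix(codes[None, :], profile.k)
    return float(_score_batch(km, logfreq)[0])


def _select_index(scores: np.ndarray, rng: np.random.Generator) -> int:
    """Weighted draw with weight exp(score - max score); uniform fallback."""
    weights = np.exp(scores - scores.max())
    total = weights.sum()
    if not np.isfinite(total) or total <= 0:
        return int(rng.integers(0, len(scores)))
    u = rng.random() * total
    return int(min(np.searchsorted(np.cumsum(weights), u, side="right"),
                   len(scores) - 1))


def select_candidate(scores: Sequence[float], rng: np.random.Generator) -> int:
    """Choose one candidate index from log-scores by a weighted random draw.

    Weights are ``exp(score - max score)``, so in the single-differing-
    position case the selection probability is exactly proportional to the
    positional frequency. All-zero weights fall back to a uniform choice.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot select from an empty candidate list")
    return _select_index(arr, rng)


# ---------------------------------------------------------------------------
# Simulation pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """All tunables of a simulation run.

    candidate_count
        Number of candidates scored per input read (the paper's "sens",
        default 50): fewer is faster, more gives closer profile fidelity.
    k
        k-mer length of the profile; 1 means single nucleotides.
    adjustment_fraction
        Fraction of the simulated-minus-target profile difference subtracted
        from the working profile at each checkpoint (default 0.5 — half of
        the difference).
    n_checkpoints
        Number of equal slices of the run after which the working profile is
        re-adjusted (default 10: after every 10% of reads; no adjustment
        after the final read).
    """

    candidate_count: int = DEFAULT_CANDIDATE_COUNT
    k: int = 1
    adjustment_fraction: float = 0.5
    n_checkpoints: int = 10
    seed: Optional[int] = None
    source_mode: str = "reference"  # or "input_sequencing"
    regions: Optional[Sequence[GenomicInterval]] = None
    quality_mode: str = "copy"  # or "constant"
    quality_char: str = "I"
    adjust: bool = True

    def __post_init__(self) -> None:
        if self.candidate_count < 1:
            raise ValidationError(
                f"candidate_count must be >= 1, got {self.candidate_count}"
            )
        if not (0 < self.adjustment_fraction <= 1):
            raise ValidationError(
                f"adjustment_fraction must be in (0, 1], got "
                f"{self.adjustment_fraction}"
            )
        if self.n_checkpoints < 1:
            raise ValidationError(
                f"n_checkpoints must be >= 1, got {self.n_checkpoints}"
            )
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if self.source_mode not in ("reference", "input_sequencing"):
            raise ValidationError(f"unknown source_mode {self.source_mode!r}")
        if self.quality_mode not in ("copy", "constant"):
            raise ValidationError(f"unknown quality_mode {self.quality_mode!r}")
        if self.quality_mode == "constant" and len(self.quality_char) != 1:
            raise ValidationError("quality_char must be a single character")
        if self.source_mode == "input_sequencing" and self.regions is not None:
            raise ValidationError(
                "region restriction applies to reference sampling only"
            )


@dataclass(frozen=True)
class SimulatedRead:
    """One generated read, paired 1:1 with a retained input read."""

    id: str
    sequence: str
    quality: Optional[str] = None
    interval: Optional[GenomicInterval] = None
    paired_input_index: int = 0

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValidationError(
                f"read {self.id!r}: quality/sequence length mismatch"
            )
        if self.interval is not None and len(self.interval) != len(self.sequence):
            raise ValidationError(
                f"read {self.id!r}: interval span != sequence length"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RunSummary:
    """Counts and convergence diagnostics of one simulation run."""

    reads_in: int
    reads_discarded: int
    reads_simulated: int
    final_distance: float
    elapsed_seconds: float
    checkpoint_distances: List[Tuple[int, float]] = field(default_factory=list)
    config: Optional[SimulationConfig] = None


def filter_ambiguous(
    reads: Sequence[ReadRecord],
) -> Tuple[List[ReadRecord], int]:
    """Drop reads containing ambiguous bases (anything outside A/C/G/T).

    Returns the retained reads (input order preserved) and the discarded
    count; raises if nothing survives.
    """
    retained = [r for r in reads if set(r.sequence) <= set("ACGT")]
    discarded = len(reads) - len(retained)
    if not retained:
        raise SimulationError(
            f"all {len(reads)} input reads contain ambiguous bases; "
            "nothing to simulate"
        )
    return retained, discarded


def _profile_from_counts(
    counts: Dict[int, np.ndarray], n_sim: Dict[int, int], k: int
) -> NucleotideProfile:
    freqs = {L: counts[L] / n_sim[L] for L in counts if n_sim[L] > 0}
    return NucleotideProfile(
        k=k, freqs=freqs, n_reads={L: n_sim[L] for L in freqs}
    )


def simulate(
    input_reads: Sequence[ReadRecord],
    source: Union[ReferenceGenome, Sequence[ReadRecord]],
    config: SimulationConfig,
) -> Tuple[List[SimulatedRead], RunSummary]:
    """Generate one simulated read per retained input read.

    The working profile starts equal to the target profile of the retained
    input reads; each input read spawns ``config.candidate_count`` candidates
    of its own length from the source, scored against the working profile,
    and one winner is chosen by a score-weighted draw. After every
    ``1/n_checkpoints`` slice of the reads the working profile is adjusted by
    :func:`adjust_profile` toward the target using the cumulative profile of
    all reads simulated so far (never after the final read). A single seeded
    generator drives every draw in a fixed order, so identical inputs and
    seed give identical output.
    """
    t0 = time.perf_counter()
    retained, discarded = filter_ambiguous(input_reads)

    if config.source_mode == "reference":
        if not isinstance(source, ReferenceGenome):
            raise ValidationError(
                "source_mode 'reference' requires a ReferenceGenome source"
            )
        sampler: Union[_GenomeSampler, _ReadsSampler] = _GenomeSampler(
            source, config.regions
        )
    else:
        if isinstance(source, ReferenceGenome):
            raise ValidationError(
                "source_mode 'input_sequencing' requires source reads, "
                "not a reference genome"
            )
        sampler = _ReadsSampler(source)

    rng = np.random.default_rng(config.seed)
    target = compute_profile(retained, config.k)
    working = target.copy()
    logfreq_cache: Dict[int, np.ndarray] = {}

    n_cols = 4**config.k
    sim_counts: Dict[int, np.ndarray] = {
        L: np.zeros((L - config.k + 1, n_cols), dtype=np.int64)
        for L in target.freqs
    }
    sim_nreads: Dict[int, int] = {L: 0 for L in target.freqs}

    n = len(retained)
    step = max(1, n // config.n_checkpoints)
    checkpoint_distances: List[Tuple[int, float]] = []

    chosen_codes: List[np.ndarray] = []
    chosen_intervals: List[Optional[GenomicInterval]] = []

    for i, read in enumerate(retained):
        L = len(read.sequence)
        codes, intervals = sampler.draw(L, config.candidate_count, rng)
        km = _kmer_index_matrix(codes, config.k)
        logfreq = logfreq_cache.get(L)
        if logfreq is None:
            logfreq = np.log(working.freqs[L] + PSEUDOCOUNT)
            logfreq_cache[L] = logfreq
        scores = _score_batch(km, logfreq)
        j = _select_index(scores, rng)
        chosen_codes.append(codes[j])
        chosen_intervals.append(intervals[j] if intervals is not None else None)
        sim_counts[L][np.arange(L - config.k + 1), km[j]] += 1
        sim_nreads[L] += 1

        done = i + 1
        if config.adjust and done < n and done % step == 0:
            sim_profile = _profile_from_counts(sim_counts, sim_nreads, config.k)
            working = adjust_profile(
                working, sim_profile, target, config.adjustment_fraction
            )
            logfreq_cache.clear()
            dist = profile_distance(sim_profile, target)
            checkpoint_distances.append((done, dist))
            logger.info(
                "checkpoint %d/%d reads: simulated-vs-target profile "
                "distance %.4f",
                done,
                n,
                dist,
            )

    simulated: List[SimulatedRead] = []
    for i, (read, codes_i, iv) in enumerate(
        zip(retained, chosen_codes, chosen_intervals)
    ):
        if config.quality_mode == "copy":
            quality = read.quality
        else:
            quality = config.quality_char * len(read.sequence)
        simulated.append(
            SimulatedRead(
                id=f"sim_{i + 1}",
                sequence=_decode(codes_i),
                quality=quality,
                interval=iv,
                paired_input_index=i,
            )
        )

    sim_profile = _profile_from_counts(sim_counts, sim_nreads, config.k)
    final_distance = profile_distance(sim_profile, target)
    summary = RunSummary(
        reads_in=len(input_reads),
        reads_discarded=discarded,
        reads_simulated=len(simulated),
        final_distance=final_distance,
        elapsed_seconds=time.perf_counter() - t0,
        checkpoint_distances=checkpoint_distances,
        config=config,
    )
    logger.info(
        "simulated %d reads (%d discarded) in %.1fs; final profile "
        "distance %.4f",
        summary.reads_simulated,
        summary.reads_discarded,
        summary.elapsed_seconds,
        summary.final_distance,
    )
    return simulated, summary


# ---------------------------------------------------------------------------
# Synthetic fixture generation
# ---------------------------------------------------------------------------


def _validate_bias_spec(
    bias_spec: Dict[int, Dict[str, float]],
) -> Dict[int, np.ndarray]:
    """Turn a per-position base-frequency spec into full distributions.

    Bases missing from a position's entry share the remaining probability
    mass equally, so ``{18: {"T": 0.9}}`` means T with probability 0.9 and
    A/C/G with 1/30 each at position 18.
    """
    dists: Dict[int, np.ndarray] = {}
    order = "ACGT"
    for pos, spec in bias_spec.items():
        if pos < 0:
            raise ValidationError(f"bias position {pos} is negative")
        vec = np.full(4, np.nan)
        for base, freq in spec.items():
            if base not in order:
                raise ValidationError(f"bias position {pos}: unknown base {base!r}")
            if not (0 <= freq <= 1):
                raise ValidationError(
                    f"bias position {pos}: frequency {freq} outside [0, 1]"
                )
            vec[order.index(base)] = freq
        given = np.nansum(vec)
        if given > 1 + 1e-9:
            raise ValidationError(
                f"bias position {pos}: stated frequencies sum to {given} > 1"
            )
        missing = np.isnan(vec)
        if missing.any():
            vec[missing] = (1 - given) / missing.sum()
        elif not np.isclose(given, 1.0):
            raise ValidationError(
                f"bias position {pos}: full distribution sums to {given}, not 1"
            )
        dists[pos] = vec
    return dists


def generate_biased_reads(
    genome: ReferenceGenome,
    n_reads: int,
    read_lengths: Tuple[int, int],
    bias_spec: Dict[int, Dict[str, float]],
    rng: np.random.Generator,
    quality_char: str = "I",
) -> List[ReadRecord]:
    """Draw reads from a genome and inject positional base-composition biases.

    Reads are uniform forward-strand genome subsequences; at each position
    listed in ``bias_spec`` the genomic base is replaced by a base drawn from
    the stated distribution. This emulates protocol-driven positional
    nucleotide enrichment (e.g. the 3'-end thymine enrichment of XR-seq
    reads) on an otherwise unbiased background.
    """
    lo, hi = read_lengths
    if not (1 <= lo <= hi):
        raise ValidationError(f"invalid read length range {read_lengths}")
    if hi > min(genome.lengths.values()):
        raise ValidationError(
            "maximum read length exceeds the shortest chromosome"
        )
    dists = _validate_bias_spec(bias_spec)
    sampler = _GenomeSampler(genome)
    lengths = (
        np.full(n_reads, lo)
        if lo == hi
        else rng.integers(lo, hi + 1, size=n_reads)
    )
    reads: List[ReadRecord] = []
    for L in sorted(set(int(x) for x in lengths)):
        count = int((lengths == L).sum())
        codes, _ = sampler.draw(L, count, rng)
        for pos, dist in dists.items():
            if pos < L:
                codes[:, pos] = rng.choice(4, size=count, p=dist)
        for row in codes:
            reads.append(
                ReadRecord(
                    id=f"read_{len(reads) + 1}",
                    sequence=_decode(row),
                    quality=quality_char * len(row),
                )
            )
    return reads


def random_genome(
    length: int, rng: np.random.Generator, name: str = "chr1"
) -> ReferenceGenome:
    """An i.i.d. uniform-ACGT genome of the given length."""
    if length < 1:
        raise ValidationError(f"genome length must be >= 1, got {length}")
    seq = _decode(rng.integers(0, 4, size=length).astype(np.uint8))
    return ReferenceGenome({name: seq})


def make_fixtures(
    out_dir: Union[str, Path],
    genome_length: int,
    n_reads: int,
    read_lengths: Tuple[int, int],
    bias_spec: Dict[int, Dict[str, float]],
    seed: int,
) -> Tuple[Path, Path, Path]:
    """Write a synthetic genome FASTA, biased reads FASTQ, and truth profile.

    The genome is i.i.d. uniform over ACGT; reads are genome subsequences
    rewritten position-wise per ``bias_spec``; qualities are constant "I".
    Deterministic under ``seed``. Returns the three paths
    (genome.fa, reads.fq, truth_profile.tsv); the truth profile holds the
    *intended* per-position distributions, not the sampled ones.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if genome_length < read_lengths[1]:
        raise ValidationError("genome_length must be >= the maximum read length")
    rng = np.random.default_rng(seed)
    genome = random_genome(genome_length, rng)
    reads = generate_biased_reads(genome, n_reads, read_lengths, bias_spec, rng)

    genome_path = out_dir / "genome.fa"
    _write_fasta_wrapped(genome.chromosomes, genome_path)

    reads_path = out_dir / "reads.fq"
    with _open_text(reads_path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")

    # intended truth profile: uniform 0.25 except at bias positions
    dists = _validate_bias_spec(bias_spec)
    length_counts = Counter(len(r) for r in reads)
    freqs = {}
    for L, cnt in length_counts.items():
        mat = np.full((L, 4), 0.25)
        for pos, dist in dists.items():
            if pos < L:
                mat[pos] = dist
        freqs[L] = mat
    truth = NucleotideProfile(
        k=1, freqs=freqs, n_reads={L: c for L, c in length_counts.items()}
    )
    truth_path = out_dir / "truth_profile.tsv"
    dump_profile(truth, truth_path)
    return genome_path, reads_path, truth_path
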