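"""Reading coding sequences, ORF quality control and codon counting.

Input FASTA is expected to carry Ensembl-style headers (pipe- or
space-delimited); transcript and gene identifiers are recognized by their
ENS*T / ENS*G prefixes and version suffixes are stripped. A complete open
reading frame here means: length divisible by three, canonical ATG start,
one of TAA/TAG/TGA as the terminal codon, no internal stop, and only
A/C/G/T characters (ambiguity codes fail QC outright rather than being
masked, which would distort codon counts).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .genetic_code import CODON_TO_AA, STOP_CODONS

logger = logging.getLogger(__name__)

# QC failure codes
NOT_MULTIPLE_OF_3 = "not_multiple_of_3"
NO_START_CODON = "no_start_codon"
NO_TERMINAL_STOP = "no_terminal_stop"
INTERNAL_STOP = "internal_stop"
NON_ACGT = "non_acgt"
TOO_SHORT_PROTEIN = "too_short_protein"
DUPLICATE_PAIR = "duplicate_pair"

_ACGT = frozenset("ACGT")
_VERSION_RE = re.compile(r"\.\d+$")
_ENST_RE = re.compile(r"^ENS[A-Z]*T\d+(\.\d+)?$")
_ENSG_RE = re.compile(r"^ENS[A-Z]*G\d+(\.\d+)?$")


@dataclass
class TranscriptRecord:
    """One coding sequence with its Ensembl-style metadata."""

    transcript_id: str
    gene_id: str | None = None
    gene_symbol: str | None = None
    chrom: str | None = None
    start: int | None = None  # 1-based inclusive, as parsed; metadata only
    end: int | None = None
    strand: str | None = None
    cds: str = ""


@dataclass
class QcReport:
    transcript_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class CodonCounts:
    """64-codon count table for one sequence (or a pool of sequences)."""

    counts: dict[str, int]
    total: int

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)


def _strip_version(identifier: str) -> str:
    return _VERSION_RE.sub("", identifier)


def _parse_header(header: str) -> dict:
    """Extract IDs, symbol and coordinates from an Ensembl-style header.

    Accepts both pipe-delimited (``ENST..|ENSG..|SYMBOL``) and space-delimited
    (``ENST.. cds chromosome:GRCh38:1:100:200:1 gene:ENSG.. gene_symbol:X``)
    dialects.
    """
    meta: dict = {
        "transcript_id": None,
        "gene_id": None,
        "gene_symbol": None,
        "chrom": None,
        "start": None,
        "end": None,
        "strand": None,
    }
    piped = "|" in header
    tokens = re.split(r"[|\s]+", header.strip())
    prev_was_gene_id = False
    for tok in tokens:
        if not tok:
            continue
        bare = tok
        for prefix in ("transcript:", "gene:"):
            if bare.startswith(prefix):
                bare = bare[len(prefix):]
        if tok.startswith("gene_symbol:"):
            meta["gene_symbol"] = tok.split(":", 1)[1]
            prev_was_gene_id = False
            continue
        parts = tok.split(":")
        if len(parts) >= 6 and parts[0].lower() in {"chromosome", "scaffold", "primary_assembly"}:
            meta["chrom"] = parts[2]
            try:
                meta["start"] = int(parts[3])
                meta["end"] = int(parts[4])
            except ValueError:
                meta["start"] = meta["end"] = None
            meta["strand"] = parts[5]
            prev_was_gene_id = False
            continue
        if _ENST_RE.match(bare):
            if meta["transcript_id"] is None:
                meta["transcript_id"] = _strip_version(bare)
            prev_was_gene_id = False
            continue
        if _ENSG_RE.match(bare):
            if meta["gene_id"] is None:
                meta["gene_id"] = _strip_version(bare)
                prev_was_gene_id = True
            continue
        # In pipe-delimited headers the field after the gene ID is the symbol.
        if piped and prev_was_gene_id and meta["gene_symbol"] is None:
            meta["gene_symbol"] = bare
        prev_was_gene_id = False
    return meta


def parse_cds_fasta(
    path: str | Path,
    errors: list[str] | None = None,
    duplicates: list[TranscriptRecord] | None = None,
) -> list[TranscriptRecord]:
    """Read a CDS FASTA into :class:`TranscriptRecord` objects.

    Only the first occurrence of every (transcript_id, gene_id) pair is kept;
    later occurrences go to *duplicates* when a list is supplied. Entries whose
    header lacks a recognizable transcript identifier are collected into
    *errors* (or logged) rather than raising. U characters are normalized to T
    and file order is preserved.
    """
    records: list[TranscriptRecord] = []
    seen: set[tuple[str, str | None]] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description or entry.id
        meta = _parse_header(header)
        if meta["transcript_id"] is None:
            msg = f"no transcript identifier in header: {header!r}"
            if errors is not None:
                errors.append(msg)
            else:
                logger.warning("skipping entry: %s", msg)
            continue
        cds = str(entry.seq).upper().replace("U", "T")
        rec = TranscriptRecord(cds=cds, **{k: meta[k] for k in meta})
        key = (rec.transcript_id, rec.gene_id)
        if key in seen:
            if duplicates is not None:
                duplicates.append(rec)
            continue
        seen.add(key)
        records.append(rec)
    return records


def qc_filter(record: TranscriptRecord) -> QcReport:
    """Check one record against the complete-ORF rules.

    Failures are reported, never raised; ``passed`` is true iff no rule is
    violated. The check is pure: the record is not modified.
    """
    cds = record.cds
    reasons: list[str] = []
    if not _ACGT.issuperset(cds):
        reasons.append(NON_ACGT)
    if len(cds) % 3 != 0:
        reasons.append(NOT_MULTIPLE_OF_3)
    if cds[:3] != "ATG":
        reasons.append(NO_START_CODON)
    if len(cds) < 3 or cds[-3:] not in STOP_CODONS:
        reasons.append(NO_TERMINAL_STOP)
    # Internal stop: scan complete triplets, excluding the final full codon.
    n_full = len(cds) // 3
    for i in range(n_full - 1):
        if cds[3 * i: 3 * i + 3] in STOP_CODONS:
            reasons.append(INTERNAL_STOP)
            break
    return QcReport(record.transcript_id, passed=not reasons, reasons=reasons)


def translate_cds(cds: str, min_protein_length: int = 10) -> tuple[str, bool]:
    """Translate a CDS with the standard code, truncating at the first stop.

    Returns ``(protein, too_short)`` where *too_short* flags proteins shorter
    than *min_protein_length* residues for downstream exclusion.

    Raises ``ValueError`` on length not divisible by three or non-ACGT codons.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    residues = []
    for i in range(0, len(cds), 3):
        codon = cds[i: i + 3]
        if codon in STOP_CODONS:
            break
        try:
            residues.append(CODON_TO_AA[codon])
        except KeyError:
            raise ValueError(f"codon {codon!r} contains non-ACGT characters") from None
    protein = "".join(residues)
    return protein, len(protein) < min_protein_length


def count_codons(cds: str) -> CodonCounts:
    """Tally consecutive non-overlapping triplets of a CDS.

    Raises ``ValueError`` on length not divisible by three or characters
    outside A/C/G/T.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    if not _ACGT.issuperset(cds):
        raise ValueError("CDS contains characters outside A/C/G/T")
    counts = Counter(cds[i: i + 3] for i in range(0, len(cds), 3))
    return CodonCounts(counts=dict(counts), total=len(cds) // 3)


def pool_counts(counts_list: Iterable[CodonCounts]) -> CodonCounts:
    """Sum codon counts across transcripts (e.g. for a reference set)."""
    pooled: Counter = Counter()
    total = 0
    for cc in counts_list:
        pooled.update(cc.counts)
        total += cc.total
    return CodonCounts(counts=dict(pooled), total=total)


def write_qc_report(reports: Sequence[QcReport], path: str | Path) -> None:
    """QC report TSV: transcript_id, passed, reasons (semicolon-joined)."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tpassed\treasons\n")
        for r in reports:
            fh.write(f"{r.transcript_id}\t{str(r.passed).lower()}\t{';'.join(r.reasons)}\n")


def write_fasta(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    """Write retained records as single-line FASTA keyed by transcript ID."""
    with open(path, "w") as fh:
        for rec in records:
            gene = rec.gene_id or ""
            fh.write(f">{rec.transcript_id}|{gene}\n{rec.cds}\n")
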