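"""Alignment containers and the read/translate/concatenate/filter operations.

Internally an alignment is a taxa-by-columns matrix of single characters
over a declared alphabet plus the gap ('-') and missing ('?') symbols.
Coordinates are 0-based half-open internally; anything reported to a user
is 1-based inclusive.  Taxon order is preserved from first input and all
joins are by label, never by row index.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabets import GAP, MISSING, resolve
from .codes import STOP, GeneticCode

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, duplicate labels, ...)."""


class Alignment:
    """A taxa x columns character matrix over a declared alphabet.

    Parameters
    ----------
    taxon_ids:
        Ordered, unique sequence labels.
    data:
        Either a list of equal-length strings or a 2-D ``<U1`` numpy array.
    alphabet:
        One of ``nt4``, ``aa20``, ``ry2``, ``aa6``, ``aa4``.
    partitions:
        Optional list of ``(name, start, end)`` half-open column ranges
        recording gene boundaries after concatenation.
    """

    def __init__(
        self,
        taxon_ids: Sequence[str],
        data,
        alphabet: str,
        partitions: list[tuple[str, int, int]] | None = None,
    ) -> None:
        self.taxon_ids = list(taxon_ids)
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise AlignmentError("duplicate taxon labels")
        if isinstance(data, np.ndarray):
            mat = np.asarray(data, dtype="<U1")
        else:
            rows = [list(str(r)) for r in data]
            lengths = {len(r) for r in rows}
            if len(lengths) > 1:
                raise AlignmentError(f"ragged rows: lengths {sorted(lengths)}")
            mat = np.array(rows, dtype="<U1") if rows else np.empty((0, 0), dtype="<U1")
        if mat.ndim != 2:
            mat = mat.reshape(len(self.taxon_ids), -1)
        if mat.shape[0] != len(self.taxon_ids):
            raise AlignmentError("row count does not match taxon count")
        self.data = mat
        self.alphabet = alphabet.lower()
        resolve(self.alphabet)
        self.partitions = partitions
        self.validate()

    # -- basic accessors ------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> str:
        return "".join(self.data[self.taxon_ids.index(taxon)])

    def rows(self) -> dict[str, str]:
        return {t: "".join(self.data[i]) for i, t in enumerate(self.taxon_ids)}

    def validate(self) -> None:
        allowed = set(resolve(self.alphabet)) | {GAP, MISSING}
        bad = set(np.unique(self.data)) - allowed
        if bad:
            raise AlignmentError(
                f"symbols {sorted(bad)} outside alphabet {self.alphabet!r}"
            )

    def take_columns(self, index) -> "Alignment":
        """New alignment restricted to the given column indices (order kept)."""
        return Alignment(self.taxon_ids, self.data[:, index], self.alphabet)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxon_ids == other.taxon_ids
            and self.alphabet == other.alphabet
            and self.data.shape == other.data.shape
            and bool((self.data == other.data).all())
        )

    def __repr__(self) -> str:
        return (
            f"<Alignment {self.n_taxa} taxa x {self.n_columns} cols"
            f" [{self.alphabet}]>"
        )


class CodonAlignment(Alignment):
    """An in-frame nucleotide alignment bound to a genetic code.

    The frame is anchored at column 0 and the column count must be a
    multiple of three.  In-frame translation must contain no internal stop
    in any complete (gap-free) codon.
    """

    def __init__(self, taxon_ids, data, code: GeneticCode, partitions=None) -> None:
        super().__init__(taxon_ids, data, "nt4", partitions)
        if self.n_columns % 3 != 0:
            raise AlignmentError(
                f"codon alignment length {self.n_columns} not divisible by 3"
            )
        self.code = code
        self._check_stops()

    @property
    def n_codons(self) -> int:
        return self.n_columns // 3

    def codon(self, taxon: str, codon_index: int) -> str:
        i = self.taxon_ids.index(taxon)
        return "".join(self.data[i, 3 * codon_index : 3 * codon_index + 3])

    def _check_stops(self) -> None:
        for i, taxon in enumerate(self.taxon_ids):
            row = self.data[i]
            for c in range(self.n_codons):
                codon = "".join(row[3 * c : 3 * c + 3])
                if any(s in (GAP, MISSING) for s in codon):
                    continue
                if self.code.translate_codon(codon) == STOP:
                    raise AlignmentError(
                        f"internal stop codon {codon} in taxon {taxon!r} at "
                        f"codon {c + 1} (columns {3 * c + 1}-{3 * c + 3})"
                    )

    def as_alignment(self) -> Alignment:
        return Alignment(self.taxon_ids, self.data, "nt4", self.partitions)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_alignment(path, alphabet: str) -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment.

    Symbols outside the declared alphabet (other than gap/missing) are
    mapped to '?' and counted in a logged warning; 'X' in amino-acid data
    is the typical case.
    """
    with open(path) as fh:
        head = fh.read(1)
    if head == "":
        raise AlignmentError(f"empty alignment file: {path}")
    fmt = "fasta" if head == ">" else "phylip-relaxed"
    if fmt == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
        pairs = [(r.id, str(r.seq).upper()) for r in records]
    else:
        from Bio import AlignIO

        msa = AlignIO.read(path, fmt)
        pairs = [(r.id, str(r.seq).upper()) for r in msa]
    if not pairs:
        raise AlignmentError(f"no sequences found in {path}")
    names = [p[0] for p in pairs]
    lengths = {len(p[1]) for p in pairs}
    if len(lengths) > 1:
        raise AlignmentError(f"ragged rows in {path}: lengths {sorted(lengths)}")
    allowed = set(resolve(alphabet)) | {GAP, MISSING}
    cleaned = []
    n_unknown = 0
    for _, seq in pairs:
        chars = list(seq)
        for j, ch in enumerate(chars):
            if ch not in allowed:
                chars[j] = MISSING
                n_unknown += 1
        cleaned.append("".join(chars))
    if n_unknown:
        logger.warning(
            "%s: %d symbols outside alphabet %r mapped to '?'", path, n_unknown, alphabet
        )
    aln = Alignment(names, cleaned, alphabet)
    aln.unknown_symbol_count = n_unknown  # type: ignore[attr-defined]
    return aln


def write_alignment(alignment: Alignment, path, fmt: str = "fasta") -> None:
    """Write FASTA (default) or relaxed PHYLIP for external tools."""
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in alignment.rows().items()
    ]
    if fmt == "fasta":
        SeqIO.write(records, path, "fasta")
    elif fmt in ("phylip", "phylip-relaxed"):
        from Bio import AlignIO
        from Bio.Align import MultipleSeqAlignment

        AlignIO.write(MultipleSeqAlignment(records), path, "phylip-relaxed")
    else:
        raise ValueError(f"unsupported output format {fmt!r}")


def read_cds_from_genbank(path) -> dict[str, str]:
    """Extract CDS nucleotide sequences from a GenBank flat file.

    Returns gene-name -> sequence for every CDS feature; used by the
    optional accession-based checks, never by the synthetic pipeline.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            name = feat.qualifiers.get("gene", feat.qualifiers.get("product", ["?"]))[0]
            out[name] = str(feat.extract(rec.seq)).upper()
    return out


# ----------------------------------------------------------------------
# Translation
# ----------------------------------------------------------------------

def translate(codon_alignment: CodonAlignment) -> Alignment:
    """Translate an in-frame codon alignment to amino acids.

    A codon containing any gap or missing symbol translates to '?'.  A
    complete codon that is a stop raises, naming the taxon and the 1-based
    codon position.
    """
    code = codon_alignment.code
    n = codon_alignment.n_codons
    rows = []
    for i, taxon in enumerate(codon_alignment.taxon_ids):
        row = codon_alignment.data[i]
        aas = []
        for c in range(n):
            codon = "".join(row[3 * c : 3 * c + 3])
            if any(s in (GAP, MISSING) for s in codon):
                aas.append(MISSING)
                continue
            aa = code.translate_codon(codon)
            if aa == STOP:
                raise AlignmentError(
                    f"stop codon {codon} for taxon {taxon!r} at codon {c + 1}"
                )
            aas.append(aa)
        rows.append("".join(aas))
    return Alignment(codon_alignment.taxon_ids, rows, "aa20")


def reverse_translate(
    aa_alignment: Alignment,
    cds_by_taxon: Mapping[str, str],
    code: GeneticCode,
) -> CodonAlignment:
    """Expand an aligned protein back onto its source codons.

    Each taxon's unaligned CDS must translate exactly to its ungapped
    amino-acid row (a single trailing stop codon on the CDS is tolerated
    and dropped).  Amino-acid gaps become '---', missing become '???'.
    """
    rows = []
    for taxon in aa_alignment.taxon_ids:
        if taxon not in cds_by_taxon:
            raise AlignmentError(f"no CDS provided for taxon {taxon!r}")
        cds = cds_by_taxon[taxon].upper().replace("U", "T")
        aa_row = aa_alignment.row(taxon)
        n_res = sum(1 for a in aa_row if a not in (GAP, MISSING))
        if len(cds) == 3 * (n_res + 1) and code.translate_codon(cds[-3:]) == STOP:
            cds = cds[:-3]
        if len(cds) != 3 * n_res:
            raise AlignmentError(
                f"CDS length {len(cds)} for taxon {taxon!r} does not match "
                f"{n_res} aligned residues"
            )
        out = []
        k = 0
        for pos, aa in enumerate(aa_row):
            if aa == GAP:
                out.append(GAP * 3)
            elif aa == MISSING:
                out.append(MISSING * 3)
            else:
                codon = cds[3 * k : 3 * k + 3]
                got = code.translate_codon(codon)
                if got != aa:
                    raise AlignmentError(
                        f"CDS/protein mismatch for taxon {taxon!r} at residue "
                        f"{pos + 1}: codon {codon} -> {got}, alignment has {aa}"
                    )
                out.append(codon)
                k += 1
        rows.append("".join(out))
    return CodonAlignment(aa_alignment.taxon_ids, rows, code)


# ----------------------------------------------------------------------
# Concatenation and column filters
# ----------------------------------------------------------------------

def concatenate(alignments: Sequence[Alignment], names: Sequence[str] | None = None) -> Alignment:
    """Concatenate per-gene alignments column-wise, recording partitions.

    All inputs must share the same taxon set and alphabet; a taxon present
    in one gene but missing from another is an error (no silent padding).
    """
    if not alignments:
        raise AlignmentError("nothing to concatenate")
    first = alignments[0]
    ref = set(first.taxon_ids)
    for aln in alignments[1:]:
        if set(aln.taxon_ids) != ref:
            raise AlignmentError("mismatched taxon sets across genes")
        if aln.alphabet != first.alphabet:
            raise AlignmentError("mismatched alphabets across genes")
    names = list(names) if names else [f"gene{i + 1}" for i in range(len(alignments))]
    order = first.taxon_ids
    blocks = []
    partitions = []
    start = 0
    for name, aln in zip(names, alignments):
        idx = [aln.taxon_ids.index(t) for t in order]
        blocks.append(aln.data[idx])
        partitions.append((name, start, start + aln.n_columns))
        start += aln.n_columns
    data = np.concatenate(blocks, axis=1) if blocks else first.data
    return Alignment(order, data, first.alphabet, partitions=partitions)


def _gap_mask(data: np.ndarray) -> np.ndarray:
    return (data == GAP) | (data == MISSING)


def filter_gap_columns(alignment: Alignment, max_gap_fraction: float) -> Alignment:
    """Keep columns whose gap+missing fraction is <= the threshold.

    For a :class:`CodonAlignment` the filter operates on whole codons to
    preserve frame: a triple is gapped wherever any of its three columns
    is gapped in a row, and the triple is kept only if the fraction of
    rows with any gap in the triple is within the threshold.
    """
    if not 0 <= max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    gaps = _gap_mask(alignment.data)
    if isinstance(alignment, CodonAlignment):
        n = alignment.n_codons
        triple_gapped = gaps.reshape(alignment.n_taxa, n, 3).any(axis=2)
        frac = triple_gapped.mean(axis=0)
        keep_codons = np.nonzero(frac <= max_gap_fraction)[0]
        cols = np.concatenate([np.arange(3 * c, 3 * c + 3) for c in keep_codons]) if len(
            keep_codons
        ) else np.array([], dtype=int)
        return CodonAlignment(
            alignment.taxon_ids, alignment.data[:, cols], alignment.code
        )
    frac = gaps.mean(axis=0)
    keep = frac <= max_gap_fraction
    return alignment.take_columns(np.nonzero(keep)[0])


def strip_incomplete_columns(alignment: Alignment) -> Alignment:
    """Keep only columns with zero gaps and zero missing symbols."""
    gaps = _gap_mask(alignment.data)
    keep = ~gaps.any(axis=0)
    if not keep.any():
        logger.warning("strip_incomplete_columns: no complete columns remain")
    if isinstance(alignment, CodonAlignment):
        n = alignment.n_codons
        keep_codons = keep.reshape(n, 3).all(axis=1)
        cols = np.nonzero(np.repeat(keep_codons, 3))[0]
        return CodonAlignment(
            alignment.taxon_ids, alignment.data[:, cols], alignment.code
        )
    return alignment.take_columns(np.nonzero(keep)[0])


def read_group_map(path) -> dict[str, str]:
    """Read a two-column TSV mapping taxon label -> group label."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise AlignmentError(f"bad group-map line: {line!r}")
            out[parts[0]] = parts[1]
    return out
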