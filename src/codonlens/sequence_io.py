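"""FASTA input with coding-sequence QC, and TSV/JSON report output.

Records are normalized to the uppercase RNA alphabet on read.  QC covers the
defects that matter for codon counting: out-of-frame length, internal stop
codons, ambiguity letters, and a missing terminal stop.  The first three make
a record "failing"; a missing terminal stop is recorded but tolerated, since
annotation pipelines differ on whether the stop is part of the CDS.

Under the ``keep`` policy, out-of-frame records are truncated at the last
complete codon so downstream counts stay well defined.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import (
    AMBIGUOUS_BASES,
    RNA_BASES,
    GeneticCode,
    normalize_rna,
    standard_code,
    to_dna,
)

FLAG_FRAME = "not-multiple-of-3"
FLAG_INTERNAL_STOP = "internal-stop"
FLAG_AMBIGUOUS = "ambiguous-bases"
FLAG_MISSING_STOP = "missing-stop"
FLAG_TRUNCATED = "truncated-to-frame"

#: Flags that make a record fail strict QC (missing-stop alone does not).
FAILING_FLAGS = frozenset({FLAG_FRAME, FLAG_INTERNAL_STOP, FLAG_AMBIGUOUS})

QC_POLICIES = ("strict", "skip", "keep")


class SequenceIOError(ValueError):
    """Unreadable, empty, or malformed sequence input."""


class QcError(SequenceIOError):
    """A record failed QC under the strict policy."""


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence: identifier, RNA-alphabet sequence, QC flags."""

    id: str
    seq: str
    qc_flags: FrozenSet[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "seq", normalize_rna(self.seq))

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3


@dataclass
class QcSummary:
    """Per-flag counts and dispositions from one FASTA read."""

    n_input: int = 0
    n_accepted: int = 0
    n_excluded: int = 0
    flag_counts: Dict[str, int] = field(default_factory=dict)
    excluded_ids: List[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_accepted": self.n_accepted,
            "n_excluded": self.n_excluded,
            "flag_counts": dict(self.flag_counts),
            "excluded_ids": list(self.excluded_ids),
        }


def qc_flags_for(seq: str, code: Optional[GeneticCode] = None) -> FrozenSet[str]:
    """Compute QC flags for a normalized RNA sequence.

    Idempotent: flags depend only on the sequence content.
    """
    code = code or standard_code()
    seq = normalize_rna(seq)
    flags = set()
    bad = {b for b in seq if b not in RNA_BASES}
    if bad:
        unknown = bad - AMBIGUOUS_BASES
        if unknown:
            raise SequenceIOError(
                f"sequence contains non-nucleotide characters {sorted(unknown)}"
            )
        flags.add(FLAG_AMBIGUOUS)
    if len(seq) % 3:
        flags.add(FLAG_FRAME)
    frame = seq[: 3 * (len(seq) // 3)]
    codons = [frame[i : i + 3] for i in range(0, len(frame), 3)]
    stops = [i for i, c in enumerate(codons) if code.codon_to_aa.get(c) == "*"]
    if any(i < len(codons) - 1 for i in stops):
        flags.add(FLAG_INTERNAL_STOP)
    if not codons or code.codon_to_aa.get(codons[-1]) != "*":
        flags.add(FLAG_MISSING_STOP)
    return frozenset(flags)


def _dedupe_ids(ids: Sequence[str]) -> List[str]:
    seen: Counter = Counter()
    out = []
    for i in ids:
        seen[i] += 1
        out.append(i if seen[i] == 1 else f"{i}__dup{seen[i]}")
    dups = [i for i, n in seen.items() if n > 1]
    if dups:
        warnings.warn(
            f"duplicate FASTA ids de-duplicated with __dupN suffix: {sorted(dups)}"
        )
    return out


def read_cds_fasta(
    path,
    qc_policy: str = "strict",
    code: Optional[GeneticCode] = None,
) -> Tuple[List[CdsRecord], QcSummary]:
    """Read a multi-FASTA of coding sequences with QC.

    Policies: ``strict`` raises on the first failing record; ``skip`` drops
    failing records (counted in the summary); ``keep`` retains them with
    flags, truncating out-of-frame records to the last complete codon.
    """
    if qc_policy not in QC_POLICIES:
        raise ValueError(f"qc_policy must be one of {QC_POLICIES}, got {qc_policy!r}")
    code = code or standard_code()
    path = Path(path)
    if not path.exists():
        raise SequenceIOError(f"FASTA file not found: {path}")
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise SequenceIOError(f"no FASTA records in {path}")

    summary = QcSummary(n_input=len(raw))
    ids = _dedupe_ids([r.id for r in raw])
    records: List[CdsRecord] = []
    for rid, rec in zip(ids, raw):
        seq = normalize_rna(str(rec.seq))
        flags = qc_flags_for(seq, code)
        for f in flags:
            summary.flag_counts[f] = summary.flag_counts.get(f, 0) + 1
        failing = flags & FAILING_FLAGS
        if failing:
            if qc_policy == "strict":
                raise QcError(
                    f"record {rid!r} failed QC ({sorted(failing)}); "
                    f"summary so far: {summary.as_dict()}"
                )
            if qc_policy == "skip":
                summary.n_excluded += 1
                summary.excluded_ids.append(rid)
                continue
            # keep: truncate to frame so counting is well defined
            if FLAG_FRAME in flags:
                seq = seq[: 3 * (len(seq) // 3)]
                flags = flags | {FLAG_TRUNCATED}
        records.append(CdsRecord(id=rid, seq=seq, qc_flags=flags))
        summary.n_accepted += 1
    return records, summary


def write_cds_fasta(records: Iterable[CdsRecord], path, alphabet: str = "dna") -> None:
    """Write records as FASTA, in DNA (default) or RNA letters."""
    conv = to_dna if alphabet == "dna" else normalize_rna
    seqs = [SeqRecord(Seq(conv(r.seq)), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def write_table(
    rows,
    path,
    format: str = "tsv",
    float_precision: int = 4,
    allow_empty: bool = False,
    columns: Optional[Sequence[str]] = None,
) -> None:
    """Write a tabular report deterministically as TSV or JSON.

    ``rows`` is a DataFrame or a list of dicts.  Column order follows
    ``columns`` if given, else first-seen order.  Floats are fixed to
    ``float_precision`` decimals so repeated writes are byte-identical.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        rows = list(rows)
        if not rows and not allow_empty:
            raise ValueError("refusing to write an empty table (allow_empty=False)")
        df = pd.DataFrame(rows, columns=columns)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    if df.empty and not allow_empty:
        raise ValueError("refusing to write an empty table (allow_empty=False)")

    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_precision}f")
    elif format == "json":
        recs = json.loads(df.to_json(orient="records", double_precision=float_precision))
        path.write_text(json.dumps(recs, indent=2, sort_keys=False) + "\n")
    else:
        raise ValueError(f"unknown table format {format!r}")


def read_table(path, format: str = "tsv") -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return pd.DataFrame(json.loads(path.read_text()))
    raise ValueError(f"unknown table format {format!r}")
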