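"""Antigen sequences, per-residue labels and annotation tables.

An antigen is a plain amino-acid sequence plus parallel per-residue vectors:
an epitope state (``E``/``N``/``U`` for unlabeled), an optional exposure state
(``E``/``B``), optional solvent-accessibility values for the free and the
antibody-bound form of the protein (percent, 0-100), and arbitrary named
numeric columns produced by external per-residue predictors.

Epitope labels follow the accessibility-change rule: a residue is an epitope
when its solvent accessibility drops by at least 5 percentage points upon
antibody binding.  Exposure labels use a low 5% cut-off on the unbound
accessibility, chosen so that essentially every epitope residue counts as
exposed.

File formats: FASTA for sequences (via Biopython) and a small TSV dialect for
per-residue annotations -- header ``record_id  position  <name> ...``,
positions 1-based, ``.`` for missing values.  Positions are 0-based
everywhere inside the library.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
#: Unknown / non-standard residue placeholder.
UNKNOWN = "X"
#: IUPAC ambiguity codes tolerated on input; all are mapped to ``X``.
AMBIGUOUS = set("BZJUO*X")

EPITOPE_STATES = ("E", "N")
EXPOSURE_STATES = ("E", "B")

#: Accessibility-drop threshold (percentage points) for epitope assignment.
EPITOPE_ACC_THRESHOLD = 5.0
#: Unbound-accessibility threshold (percent) separating exposed from buried.
EXPOSURE_ACC_THRESHOLD = 5.0


class FormatError(ValueError):
    """Malformed input file (FASTA or annotation table)."""


class MissingDataError(ValueError):
    """A required per-residue annotation is absent."""


@dataclass
class AntigenRecord:
    """One antigen chain with its per-residue annotations.

    All per-residue vectors have exactly ``len(sequence)`` entries.
    """

    id: str
    sequence: str
    labels: str = ""
    exposure: str = ""
    acc_unbound: np.ndarray | None = None
    acc_bound: np.ndarray | None = None
    extra_features: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS) - {UNKNOWN}
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal residue characters {sorted(bad)}"
            )
        n = len(self.sequence)
        if not self.labels:
            self.labels = "U" * n
        if len(self.labels) != n or set(self.labels) - {"E", "N", "U"}:
            raise FormatError(f"record {self.id!r}: bad label string")
        if self.exposure and (
            len(self.exposure) != n or set(self.exposure) - {"E", "B", "U"}
        ):
            raise FormatError(f"record {self.id!r}: bad exposure string")
        for name in ("acc_unbound", "acc_bound"):
            acc = getattr(self, name)
            if acc is not None:
                acc = np.asarray(acc, dtype=float)
                if acc.shape != (n,):
                    raise FormatError(
                        f"record {self.id!r}: {name} length {acc.shape} != {n}"
                    )
                finite = acc[np.isfinite(acc)]
                if finite.size and (finite.min() < 0 or finite.max() > 100):
                    raise FormatError(
                        f"record {self.id!r}: {name} outside [0, 100]"
                    )
                setattr(self, name, acc)
        for cname, col in list(self.extra_features.items()):
            col = np.asarray(col, dtype=float)
            if col.shape != (n,):
                raise FormatError(
                    f"record {self.id!r}: column {cname!r} length mismatch"
                )
            self.extra_features[cname] = col

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Corpus:
    """An ordered collection of antigen records with unique ids."""

    records: list[AntigenRecord]
    name: str = "corpus"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate record ids: {dup}")
        self._by_id = {r.id: r for r in self.records}

    def __iter__(self) -> Iterator[AntigenRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rid: str) -> AntigenRecord:
        return self._by_id[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self._by_id

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.records)

    def subset(self, ids: list[str], name: str | None = None) -> "Corpus":
        """Sub-corpus of the given record ids, keeping their given order."""
        return Corpus([self._by_id[i] for i in ids], name=name or self.name)


# ---------------------------------------------------------------------------
# FASTA I/O


def _clean_sequence(rid: str, raw: str) -> str:
    seq = "".join(raw.split()).upper()
    cleaned = []
    for ch in seq:
        if ch in AA_INDEX:
            cleaned.append(ch)
        elif ch in AMBIGUOUS:
            if ch != UNKNOWN:
                logger.warning(
                    "record %r: non-standard residue %r mapped to 'X'", rid, ch
                )
            cleaned.append(UNKNOWN)
        else:
            raise FormatError(
                f"record {rid!r}: illegal character {ch!r} in sequence"
            )
    return "".join(cleaned)


def read_fasta(path: str | Path, name: str | None = None) -> Corpus:
    """Read a FASTA file into a :class:`Corpus` with all labels ``U``.

    Sequences are uppercased, whitespace is stripped, and IUPAC ambiguity
    codes are mapped to ``X`` with a logged warning.  Any other character
    raises :class:`FormatError` naming the offending record.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            AntigenRecord(id=rec.id, sequence=_clean_sequence(rec.id, str(rec.seq)))
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return Corpus(records, name=name or path.stem)


def write_fasta(corpus: Corpus, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in corpus
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Per-residue annotation tables (TSV dialect)

#: Column names with dedicated fields on :class:`AntigenRecord`.
RESERVED_COLUMNS = ("acc_unbound", "acc_bound", "label", "exposure")


def read_residue_table(path: str | Path, corpus: Corpus) -> Corpus:
    """Attach per-residue numeric columns from a TSV file to ``corpus``.

    The file has a header ``record_id  position  <name1> <name2> ...`` with
    1-based positions and ``.`` for missing cells.  Columns named
    ``acc_unbound``/``acc_bound`` populate the accessibility fields,
    ``label``/``exposure`` the state strings; all other columns become
    ``extra_features`` entries (missing cells stored as NaN).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["."], dtype={"record_id": str})
    required = {"record_id", "position"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: header must contain {sorted(required)}")
    value_cols = [c for c in df.columns if c not in required]

    for rid, grp in df.groupby("record_id", sort=False):
        if rid not in corpus:
            raise FormatError(f"{path}: unknown record id {rid!r}")
        rec = corpus[rid]
        pos = grp["position"].to_numpy(dtype=int)
        if pos.min() < 1 or pos.max() > len(rec):
            bad = pos[(pos < 1) | (pos > len(rec))][0]
            raise FormatError(
                f"{path}: record {rid!r} position {bad} outside 1..{len(rec)}"
            )
        idx = pos - 1
        for cname in value_cols:
            if cname in ("label", "exposure"):
                states = grp[cname].astype("string")
                chars = list(rec.labels if cname == "label" else (rec.exposure or "U" * len(rec)))
                for i, s in zip(idx, states):
                    if pd.notna(s):
                        chars[i] = str(s)
                if cname == "label":
                    rec.labels = "".join(chars)
                else:
                    rec.exposure = "".join(chars)
                continue
            vals = grp[cname].to_numpy(dtype=float)
            if cname in ("acc_unbound", "acc_bound"):
                target = getattr(rec, cname)
                if target is None:
                    target = np.full(len(rec), np.nan)
                target[idx] = vals
                setattr(rec, cname, target)
            else:
                col = rec.extra_features.get(cname)
                if col is None:
                    col = np.full(len(rec), np.nan)
                col[idx] = vals
                rec.extra_features[cname] = col
        # re-validate ranges / lengths
        dataclasses.replace(rec)
    return corpus


def write_residue_table(
    corpus: Corpus,
    path: str | Path,
    columns: list[str] | None = None,
    float_fmt: str = "%.10g",
) -> None:
    """Write per-residue annotations for every record to the TSV dialect.

    ``columns`` defaults to every populated column (accessibilities, labels,
    exposure, extra features) in a stable order.
    """
    rows = []
    for rec in corpus:
        n = len(rec)
        data: dict[str, object] = {
            "record_id": [rec.id] * n,
            "position": np.arange(1, n + 1),
        }
        cols = columns
        if cols is None:
            cols = []
            if rec.acc_unbound is not None:
                cols.append("acc_unbound")
            if rec.acc_bound is not None:
                cols.append("acc_bound")
            if set(rec.labels) != {"U"}:
                cols.append("label")
            if rec.exposure:
                cols.append("exposure")
            cols.extend(sorted(rec.extra_features))
        for cname in cols:
            if cname == "label":
                data[cname] = list(rec.labels)
            elif cname == "exposure":
                data[cname] = list(rec.exposure or "U" * n)
            elif cname in ("acc_unbound", "acc_bound"):
                acc = getattr(rec, cname)
                data[cname] = acc if acc is not None else np.full(n, np.nan)
            else:
                data[cname] = rec.extra_features[cname]
        rows.append(pd.DataFrame(data))
    out = pd.concat(rows, ignore_index=True)
    out.to_csv(path, sep="\t", index=False, na_rep=".", float_format=float_fmt)


# ---------------------------------------------------------------------------
# Labeling rules


def assign_epitope_labels(
    record: AntigenRecord, threshold: float = EPITOPE_ACC_THRESHOLD
) -> AntigenRecord:
    """Label each residue ``E`` or ``N`` from the accessibility change.

    A residue is an epitope when ``acc_unbound - acc_bound >= threshold``
    (inclusive at the threshold); everything else, including residues that
    become *more* exposed in the complex, is ``N``.  Returns a new record.
    """
    if record.acc_unbound is None or record.acc_bound is None:
        raise MissingDataError(
            f"record {record.id!r}: both accessibility vectors are required "
            "for epitope assignment"
        )
    delta = record.acc_unbound - record.acc_bound
    labels = "".join("E" if d >= threshold else "N" for d in delta)
    return replace(record, labels=labels)


def assign_exposure_labels(
    record: AntigenRecord, threshold: float = EXPOSURE_ACC_THRESHOLD
) -> AntigenRecord:
    """Label each residue exposed (``E``) or buried (``B``).

    Exposed means the unbound accessibility is strictly higher than the
    threshold; equality counts as buried.  Returns a new record.
    """
    if record.acc_unbound is None:
        raise MissingDataError(
            f"record {record.id!r}: unbound accessibility is required "
            "for exposure assignment"
        )
    exposure = "".join("E" if a > threshold else "B" for a in record.acc_unbound)
    return replace(record, exposure=exposure)


def assign_labels(corpus: Corpus, threshold: float = 5.0) -> Corpus:
    """Apply both labeling rules to every record of a corpus."""
    recs = [
        assign_exposure_labels(assign_epitope_labels(r, threshold), threshold)
        for r in corpus
    ]
    return Corpus(recs, name=corpus.name)
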