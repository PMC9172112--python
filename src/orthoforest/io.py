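"""Data model and readers/writers for protein records and annotation tables.

The pipeline's atom is the :class:`ProteinRecord` — one protein with a
species tag, an amino-acid sequence and its functional annotation (GO terms,
Pfam domains, free-text keywords). Records are grouped into a
:class:`Dataset`, an ordered, accession-unique collection that every other
module consumes and produces.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

GO_RE = re.compile(r"^GO:\d{7}$")
PFAM_RE = re.compile(r"^PF\d{5}$")

#: 20 standard residues plus X (unknown); '-' and '*' are tolerated on input.
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
_TOLERATED = AA_ALPHABET | {"-", "*"}


class DatasetError(ValueError):
    """Raised on invariant violations while building or combining datasets."""


@dataclass
class ProteinRecord:
    """A single protein with its species tag, sequence and annotations."""

    accession: str
    species: str
    sequence: str
    name: str = ""
    go_terms: set[str] = field(default_factory=set)
    pfam_terms: set[str] = field(default_factory=set)
    keywords: set[str] = field(default_factory=set)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise DatasetError("accession must be non-empty")
        if len(self.sequence) < 1:
            raise DatasetError(f"{self.accession}: sequence must be non-empty")
        for term in self.go_terms:
            if not GO_RE.match(term):
                raise DatasetError(f"{self.accession}: malformed GO id {term!r}")
        for term in self.pfam_terms:
            if not PFAM_RE.match(term):
                raise DatasetError(f"{self.accession}: malformed Pfam id {term!r}")
        # keywords are matched case-insensitively throughout; store lowered
        self.keywords = {k.lower() for k in self.keywords}


class Dataset:
    """Ordered, accession-unique collection of :class:`ProteinRecord`.

    Parameters
    ----------
    records:
        Records in their intended order. Duplicate accessions raise.
    provenance:
        Free-text log lines describing origin and applied operations.
    """

    def __init__(
        self,
        records: Iterable[ProteinRecord] = (),
        provenance: Sequence[str] = (),
    ) -> None:
        self._records: list[ProteinRecord] = []
        self._index: dict[str, ProteinRecord] = {}
        self.provenance: list[str] = list(provenance)
        for rec in records:
            self.add(rec)

    def add(self, rec: ProteinRecord) -> None:
        if rec.accession in self._index:
            raise DatasetError(f"duplicate accession: {rec.accession!r}")
        self._records.append(rec)
        self._index[rec.accession] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._index

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._index[accession]

    @property
    def records(self) -> list[ProteinRecord]:
        return list(self._records)

    def accessions(self) -> list[str]:
        return [r.accession for r in self._records]

    def species_tags(self) -> set[str]:
        return {r.species for r in self._records}

    def subset(self, accessions: Iterable[str]) -> "Dataset":
        """Records whose accession is in ``accessions``, input order kept."""
        want = set(accessions)
        out = Dataset(
            (r for r in self._records if r.accession in want),
            provenance=self.provenance + [f"subset to {len(want)} accessions"],
        )
        return out

    def log(self, message: str) -> None:
        self.provenance.append(message)


def _split_header(header: str) -> tuple[str, str]:
    """FASTA header → (accession, name): token before first whitespace/'|'."""
    m = re.split(r"[\s|]", header, maxsplit=1)
    accession = m[0]
    name = m[1].strip() if len(m) > 1 else ""
    return accession, name


def read_fasta(path: str | Path, species: str, source: str = "") -> Dataset:
    """Read a protein FASTA file into a Dataset, tagging every record.

    The accession is the header token before the first whitespace or ``|``;
    the remainder becomes the free-text name. A trailing ``*`` (stop) is
    stripped silently; any character outside the amino-acid alphabet plus
    ``X``/``*``/``-`` is a hard error.
    """
    path = Path(path)
    ds = Dataset(provenance=[f"read_fasta {path} species={species}"])
    for entry in SeqIO.parse(str(path), "fasta"):
        accession, name = _split_header(entry.description)
        if not accession:
            raise DatasetError(f"{path}: empty FASTA header")
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise DatasetError(f"{path}: empty sequence for {accession!r}")
        bad = sorted(set(seq) - _TOLERATED)
        if bad:
            raise DatasetError(
                f"{path}: {accession!r} contains non-amino-acid characters {bad}"
            )
        ds.add(
            ProteinRecord(
                accession=accession,
                species=species,
                sequence=seq,
                name=name,
                source=source or str(path),
            )
        )
    return ds


def _split_multivalue(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    text = str(cell).strip()
    if not text or text.lower() == "nan":
        return []
    return [tok.strip() for tok in re.split(r"[;|]", text) if tok.strip()]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_annotation_table(path: str | Path) -> Dataset:
    """Read a delimited annotation table (CSV/TSV) into a Dataset.

    Required columns: ``accession``, ``species``. Optional: ``sequence``,
    ``name``, ``go_terms``, ``pfam_terms``, ``keywords`` (multi-valued cells
    split on ``;`` or ``|``). Malformed GO/Pfam tokens are dropped and
    counted in the provenance log, not fatal. Records lacking a sequence
    column get the 1-residue placeholder ``X`` so annotation-only tables
    remain loadable.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("accession", "species"):
        if col not in df.columns:
            raise DatasetError(f"{path}: missing required column {col!r}")
    dropped = 0
    ds = Dataset(provenance=[f"read_annotation_table {path}"])
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        accession = (row.get("accession") or "").strip() if isinstance(
            row.get("accession"), str
        ) else row.get("accession")
        if accession is None or (isinstance(accession, float) and pd.isna(accession)) or not accession:
            raise DatasetError(f"{path}: empty accession at row {i}")
        go_raw = _split_multivalue(row.get("go_terms"))
        pf_raw = _split_multivalue(row.get("pfam_terms"))
        go = {t for t in go_raw if GO_RE.match(t)}
        pf = {t for t in pf_raw if PFAM_RE.match(t)}
        dropped += (len(go_raw) - len(go)) + (len(pf_raw) - len(pf))
        seq = row.get("sequence")
        if seq is None or (isinstance(seq, float) and pd.isna(seq)) or not str(seq).strip():
            seq = "X"
        ds.add(
            ProteinRecord(
                accession=str(accession),
                species=str(row["species"]).strip(),
                sequence=str(seq).strip().upper(),
                name="" if pd.isna(row.get("name")) or row.get("name") is None else str(row.get("name")),
                go_terms=go,
                pfam_terms=pf,
                keywords=set(_split_multivalue(row.get("keywords"))),
                source=str(path),
            )
        )
    ds.log(f"dropped {dropped} malformed annotation tokens")
    ds.invalid_term_count = dropped  # type: ignore[attr-defined]
    return ds


def merge_datasets(*datasets: Dataset) -> Dataset:
    """Concatenate datasets in order; accession collisions are fatal.

    Deduplication is a separate, explicit operation
    (:func:`orthoforest.filtering.dedupe`).
    """
    if len(datasets) < 2:
        raise DatasetError("merge_datasets needs at least two datasets")
    seen: set[str] = set()
    for d in datasets:
        collisions = seen & set(d.accessions())
        if collisions:
            raise DatasetError(
                f"accession collision on merge: {sorted(collisions)[:10]}"
            )
        seen |= set(d.accessions())
    provenance: list[str] = []
    for d in datasets:
        provenance += d.provenance
    sizes = "+".join(str(len(d)) for d in datasets)
    merged = Dataset(provenance=provenance + [f"merge_datasets {sizes}"])
    for d in datasets:
        for rec in d:
            merged.add(rec)
    return merged


def dataset_to_rows(d: Dataset) -> list[dict[str, str]]:
    """Flatten a Dataset to table rows (term sets sorted, ';'-joined)."""
    return [
        {
            "accession": r.accession,
            "species": r.species,
            "sequence": r.sequence,
            "name": r.name,
            "go_terms": ";".join(sorted(r.go_terms)),
            "pfam_terms": ";".join(sorted(r.pfam_terms)),
            "keywords": ";".join(sorted(r.keywords)),
        }
        for r in d
    ]


def write_table(
    rows: Sequence[Mapping[str, object]] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> Path:
    """Write result rows as a delimited table (TSV by extension default).

    Column order is deterministic: the ``columns`` argument if given, else
    first-seen key order. An empty row set still writes the header when
    ``columns`` is supplied.
    """
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        if columns is None:
            columns = []
            for row in rows:
                for k in row:
                    if k not in columns:
                        columns.append(k)
        df = pd.DataFrame(list(rows), columns=list(columns))
    df.to_csv(path, sep=_sep_for(path), index=False)
    return path


def write_fasta(d: Dataset, path: str | Path, label_species: bool = False) -> Path:
    """Write a Dataset as FASTA; ``label_species`` appends ``_<SPECIES>``
    to each accession (the tree-export labelling convention)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in d:
            label = f"{rec.accession}_{rec.species}" if label_species else rec.accession
            header = f">{label}" + (f" {rec.name}" if rec.name else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
    return path
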