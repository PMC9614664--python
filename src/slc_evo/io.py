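"""FASTA and table I/O for protein records and curated references."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import CuratedReference, ProteinRecord, check_unique_ids


def _meta(description: str) -> dict[str, str]:
    out = {}
    for token in description.split():
        if "=" in token:
            k, v = token.split("=", 1)
            out[k] = v
    return out


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA; species/clade/gene metadata is taken from
    key=value tokens in the description line (species defaults to the id)."""
    records = []
    for sr in SeqIO.parse(str(path), "fasta"):
        meta = _meta(sr.description)
        records.append(ProteinRecord(
            id=sr.id,
            species=meta.get("species", sr.id),
            clade=meta.get("clade", ""),
            gene_label=meta.get("gene", ""),
            sequence=str(sr.seq).upper()))
    check_unique_ids(records)
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    out = []
    for rec in records:
        desc = f"species={rec.species}"
        if rec.clade:
            desc += f" clade={rec.clade}"
        if rec.gene_label:
            desc += f" gene={rec.gene_label}"
        out.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    SeqIO.write(out, str(path), "fasta")


REFERENCE_COLUMNS = ["family", "side", "boundary", "sequence",
                     "conserved_sites"]


def write_references(refs: dict[str, CuratedReference],
                     path: str | Path) -> None:
    """TSV of curated references: family, side, boundary (0-based per the
    TailAnnotation convention), sequence, and semicolon-joined
    position:residue conserved sites."""
    rows = [{
        "family": r.family, "side": r.side, "boundary": r.boundary,
        "sequence": r.sequence,
        "conserved_sites": ";".join(f"{p}:{res}"
                                    for p, res in r.conserved_sites),
    } for r in refs.values()]
    pd.DataFrame(rows, columns=REFERENCE_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_references(path: str | Path) -> dict[str, CuratedReference]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    refs = {}
    for row in df.itertuples():
        sites = tuple(
            (int(tok.split(":")[0]), tok.split(":")[1])
            for tok in str(row.conserved_sites).split(";") if tok)
        refs[str(row.family)] = CuratedReference(
            family=str(row.family), sequence=str(row.sequence),
            boundary=int(row.boundary), side=str(row.side),
            conserved_sites=sites)
    return refs


def read_dh_table(path: str | Path) -> pd.DataFrame:
    """Germline DH length table: species, dh_avg, dh_max (length unit as
    configured — nucleotides by default)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"species", "dh_avg", "dh_max"} - set(df.columns)
    if missing:
        raise ValueError(f"DH table missing columns: {sorted(missing)}")
    return df.set_index("species")
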