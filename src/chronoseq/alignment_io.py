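"""Alignment writers/readers (FASTA, NEXUS) and codon translation."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Union

from Bio.Data import CodonTable

from .engine import GAP, Alignment

__all__ = ["write_fasta", "write_nexus", "read_alignment", "translate_codons"]

_FASTA_WIDTH = 80

_NEXUS_DATATYPE = {"dna": "DNA", "protein": "PROTEIN", "standard": "STANDARD"}


def write_fasta(a: Alignment, path: Union[str, Path]) -> None:
    """Write one FASTA record per taxon, 80-column wrapped."""
    a.validate()
    with open(path, "w") as fh:
        for name in a.taxa:
            fh.write(f">{name}\n")
            seq = a.rows[name]
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")


def write_nexus(a: Alignment, path: Union[str, Path], interleave: bool = False) -> None:
    """Write a NEXUS DATA block declaring NTAX/NCHAR/DATATYPE/GAP."""
    a.validate()
    datatype = _NEXUS_DATATYPE.get(a.datatype, "STANDARD")
    names = [_nexus_name(n) for n in a.taxa]
    pad = max(len(n) for n in names) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"\tDIMENSIONS NTAX={len(a.taxa)} NCHAR={a.n_columns};\n")
        fh.write(
            f"\tFORMAT DATATYPE={datatype} GAP={GAP} MISSING=?"
            + (" INTERLEAVE=YES" if interleave else "")
            + ";\n"
        )
        fh.write("\tMATRIX\n")
        if interleave:
            for start in range(0, a.n_columns, _FASTA_WIDTH):
                for raw, name in zip(a.taxa, names):
                    fh.write(f"\t{name:<{pad}}{a.rows[raw][start:start + _FASTA_WIDTH]}\n")
                fh.write("\n")
        else:
            for raw, name in zip(a.taxa, names):
                fh.write(f"\t{name:<{pad}}{a.rows[raw]}\n")
        fh.write("\t;\nEND;\n")


def _nexus_name(name: str) -> str:
    if any(c in name for c in " \t();,[]{}'\""):
        return "'" + name.replace("'", "''") + "'"
    return name


def read_alignment(path: Union[str, Path]) -> Alignment:
    """Read a FASTA or (non-interleaved or interleaved) NEXUS alignment."""
    text = Path(path).read_text()
    if text.lstrip().lower().startswith("#nexus"):
        return _read_nexus(text)
    return _read_fasta(text)


def _read_fasta(text: str) -> Alignment:
    names: List[str] = []
    rows: Dict[str, str] = {}
    current: Optional[str] = None
    chunks: List[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if current is not None:
                rows[current] = "".join(chunks)
            current = line[1:].strip()
            if current in rows or current in names:
                raise ValueError(f"duplicate FASTA record {current!r}")
            names.append(current)
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if current is not None:
        rows[current] = "".join(chunks)
    if not names:
        raise ValueError("no FASTA records found")
    aln = Alignment(names, rows, [(0, len(rows[names[0]]))], _guess_datatype(rows))
    aln.validate()
    return aln


def _read_nexus(text: str) -> Alignment:
    lines = text.splitlines()
    in_matrix = False
    datatype = "standard"
    names: List[str] = []
    rows: Dict[str, List[str]] = {}
    for line in lines:
        stripped = line.strip()
        upper = stripped.upper()
        if upper.startswith("FORMAT"):
            for token in stripped.rstrip(";").split():
                if token.upper().startswith("DATATYPE="):
                    dt = token.split("=", 1)[1].upper()
                    datatype = {"DNA": "dna", "PROTEIN": "protein"}.get(dt, "standard")
        if upper == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if stripped.startswith(";") or upper.startswith("END"):
                break
            if not stripped:
                continue
            name, seq = _split_nexus_row(stripped)
            if name not in rows:
                names.append(name)
                rows[name] = []
            rows[name].append(seq)
    if not names:
        raise ValueError("no MATRIX rows found in NEXUS input")
    flat = {n: "".join(parts) for n, parts in rows.items()}
    aln = Alignment(names, flat, [(0, len(flat[names[0]]))], datatype)
    aln.validate()
    return aln


def _split_nexus_row(line: str) -> tuple:
    if line.startswith("'"):
        end = 1
        while True:
            end = line.index("'", end)
            if line[end : end + 2] == "''":
                end += 2
                continue
            break
        name = line[1:end].replace("''", "'")
        seq = line[end + 1 :].strip()
    else:
        name, seq = line.split(None, 1)
    return name, seq.replace(" ", "")


def _guess_datatype(rows: Dict[str, str]) -> str:
    chars = set("".join(rows.values())) - {GAP, "?"}
    if chars <= set("ACGTUN"):
        return "dna"
    if chars <= set("ARNDCQEGHILKMFPSTWYVX"):
        return "protein"
    return "standard"


def translate_codons(seq: str, code_table: int = 1) -> str:
    """Translate a nucleotide string codon-by-codon to amino acids.

    Length must be divisible by 3; a fully gapped codon ``---`` becomes
    ``-``; stop codons and partially gapped codons are errors (the
    simulator's codon state space excludes stops).
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    table = CodonTable.unambiguous_dna_by_id[code_table]
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3].upper()
        if codon == GAP * 3:
            out.append(GAP)
            continue
        if GAP in codon:
            raise ValueError(f"partially gapped codon {codon!r} at position {i}")
        if codon in table.stop_codons:
            raise ValueError(f"stop codon {codon!r} at position {i}")
        try:
            out.append(table.forward_table[codon])
        except KeyError as exc:
            raise ValueError(f"unknown codon {codon!r} at position {i}") from exc
    return "".join(out)
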