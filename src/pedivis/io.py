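"""Readers and writers for pedigree tables and relatedness matrices.

Two pedigree dialects are supported:

* ``csv`` — header row required; default columns ``personID,momID,dadID,sex``
  plus optional ``famID, affected, twinID, zygosity`` and any number of
  numeric phenotype columns.  A ``columnMap`` lets callers point the standard
  names at differently-named columns.
* ``plink_fam`` — whitespace-separated ``FID IID PAT MAT SEX PHENO``; "0"
  marks a missing parent, SEX 1=male 2=female 0=unknown; the phenotype
  column is ignored.

Missing-parent codes ``"", "0", "NA"`` are normalised to the internal
missing sentinel on ingestion for both dialects.
"""

from __future__ import annotations

import io as _io
import sys
from typing import Dict, List, Optional, TextIO, Union

import numpy as np
import pandas as pd

from .ped_model import (
    Individual,
    PedigreeTable,
    Sex,
    Zygosity,
    MISSING_CODES,
    parse_affected,
    parse_sex,
)

_RESERVED = {"personID", "momID", "dadID", "sex", "famID",
             "affected", "twinID", "zygosity", "placeholder"}


def _norm_missing(value: object) -> Optional[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s in MISSING_CODES else s


def read_pedigree(
    source: Union[str, TextIO],
    dialect: str = "csv",
    columnMap: Optional[Dict[str, str]] = None,
) -> PedigreeTable:
    """Parse a pedigree file into a normalised :class:`PedigreeTable`.

    ``source`` may be a path, an open text stream, or ``"-"`` for stdin.
    Raises ``ValueError`` on duplicate personIDs or unresolvable required
    columns.
    """
    if source == "-":
        source = _io.StringIO(sys.stdin.read())
    if dialect == "csv":
        return _read_csv(source, columnMap or {})
    if dialect == "plink_fam":
        return _read_fam(source)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_csv(source, columnMap: Dict[str, str]) -> PedigreeTable:
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    cols = {columnMap.get(name, name): name for name in
            ["personID", "momID", "dadID", "sex", "famID",
             "affected", "twinID", "zygosity", "placeholder"]}
    for required in ["personID", "momID", "dadID", "sex"]:
        file_col = columnMap.get(required, required)
        if file_col not in df.columns:
            raise ValueError(
                f"required column {required!r} not found "
                f"(looked for {file_col!r}; available: {list(df.columns)})"
            )
    mapped = {c: cols[c] for c in df.columns if c in cols}
    pheno_cols = [c for c in df.columns if c not in mapped]

    individuals: List[Individual] = []
    for _, row in df.iterrows():
        def grab(std: str) -> Optional[str]:
            file_col = columnMap.get(std, std)
            if file_col not in df.columns:
                return None
            return _norm_missing(row[file_col])

        zyg = grab("zygosity")
        phenos: Dict[str, float] = {}
        for c in pheno_cols:
            v = str(row[c]).strip()
            if v not in ("", "NA", "nan"):
                phenos[c] = float(v)
        aff_raw = grab("affected")
        individuals.append(
            Individual(
                personID=str(row[columnMap.get("personID", "personID")]).strip(),
                momID=grab("momID"),
                dadID=grab("dadID"),
                sex=parse_sex(row[columnMap.get("sex", "sex")]),
                famID=grab("famID"),
                affected=None if aff_raw is None else parse_affected(aff_raw),
                twinID=grab("twinID"),
                zygosity=Zygosity(zyg) if zyg in ("MZ", "DZ") else None,
                phenotypes=phenos,
                placeholder=(grab("placeholder") == "1"),
            )
        )
    return PedigreeTable(individuals)


def _read_fam(source) -> PedigreeTable:
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    individuals: List[Individual] = []
    for ln, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f".fam line {ln}: expected >=5 fields, got {len(parts)}")
        fid, iid, pat, mat, sex = parts[:5]
        individuals.append(
            Individual(
                personID=iid,
                momID=_norm_missing(mat),
                dadID=_norm_missing(pat),
                sex=parse_sex(sex),
                famID=_norm_missing(fid),
            )
        )
    return PedigreeTable(individuals)


def write_pedigree(ped: PedigreeTable, path: Union[str, TextIO]) -> None:
    """Write the CSV dialect; the output re-reads to an identical table."""
    df = ped.to_dataframe()
    df.to_csv(path, index=False)


# -- relatedness matrix CSV --------------------------------------------------

def write_matrix(mat, path: Union[str, TextIO]) -> None:
    """CSV with ids as first row and first column; kind stored in the corner
    cell as ``kind:<kind>`` so the file round-trips."""
    df = pd.DataFrame(mat.values, index=mat.ids, columns=mat.ids)
    df.index.name = f"kind:{mat.kind}"
    df.to_csv(path)  # str(float) is round-trip exact


def read_matrix(path: Union[str, TextIO]):
    from .relatedness import RelatednessMatrix

    df = pd.read_csv(path, index_col=0)
    corner = df.index.name or ""
    kind = corner.split(":", 1)[1] if corner.startswith("kind:") else "custom"
    ids = [str(i) for i in df.index]
    return RelatednessMatrix(ids=ids, values=df.to_numpy(dtype=float), kind=kind)
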