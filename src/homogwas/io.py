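"""File I/O: cohort tables, PLINK-style genotype and eigenvector files.

Dialects follow PLINK conventions: phenotype coded 1 = healthy/control,
2 = diseased/case, 0 or -9 = missing (subject excluded with a logged
count); .eigenvec files are whitespace tables ``FID IID PC1..PCk`` with or
without a header; combined cohort TSVs require a header with columns
``FID IID PHENOTYPE PC1..PCk`` and an optional ``WEIGHT`` column.

Parsers reject malformed numeric fields with an error naming the offending
line rather than silently coercing.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np

from .homogenize import HomogenizationResult
from .pcspace import GenotypeMatrix, PCProjection
from .spheres import Cohort

logger = logging.getLogger("homogwas")

__all__ = [
    "read_cohort",
    "write_weights",
    "read_weights",
    "write_eigenvec",
    "read_raw",
    "read_vcf",
]

_MISSING_PHENO = {"0", "-9"}


def _parse_float(token: str, path: str, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"{path}:{lineno}: malformed numeric {what} field {token!r}"
        ) from None


def _read_table(path: str | Path) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            rows.append((lineno, line.split()))
    if not rows:
        raise ValueError(f"{path}: empty file")
    return rows


def _eigenvec_rows(path: str | Path):
    """Yield (lineno, fid, iid, pcs) from an eigenvec file, header optional."""
    rows = _read_table(path)
    first = rows[0][1]
    header = first[0].lstrip("#").upper() == "FID" or first[0].upper() in {"FID", "#FID"}
    if header:
        rows = rows[1:]
    for lineno, toks in rows:
        if len(toks) < 3:
            raise ValueError(f"{path}:{lineno}: expected FID IID PC1..., got {len(toks)} fields")
        pcs = [_parse_float(t, str(path), lineno, "PC") for t in toks[2:]]
        yield lineno, toks[0], toks[1], pcs


def read_cohort(
    path: str | Path | None = None,
    eigenvec: str | Path | None = None,
    pheno: str | Path | None = None,
) -> Cohort:
    """Read a cohort from a combined TSV or an eigenvec + phenotype pair.

    The combined TSV needs a header ``FID IID PHENOTYPE PC1..PCk [WEIGHT]``.
    The phenotype file is ``FID IID PHENO`` (header optional). Subjects with
    missing phenotype codes are excluded; the count is logged.
    """
    if path is not None:
        return _read_combined(path)
    if eigenvec is None or pheno is None:
        raise ValueError("give either a combined TSV path or eigenvec + pheno paths")
    return _read_pair(eigenvec, pheno)


def _pheno_from_code(code: str, path: str, lineno: int) -> bool | None:
    if code in _MISSING_PHENO:
        return None
    if code == "2":
        return True
    if code == "1":
        return False
    raise ValueError(f"{path}:{lineno}: unknown phenotype code {code!r} (expect 1/2/0/-9)")


def _finalize(fids, iids, dis, coords, weights, n_missing, src) -> Cohort:
    if n_missing:
        logger.warning("%s: excluded %d subject(s) with missing phenotype", src, n_missing)
        warnings.warn(f"excluded {n_missing} subject(s) with missing phenotype", stacklevel=3)
    if len(iids) == 0:
        raise ValueError(f"{src}: no subjects with a valid phenotype")
    keys = list(zip(fids, iids))
    if len(set(keys)) != len(keys):
        raise ValueError(f"{src}: duplicate (FID, IID) keys")
    return Cohort(
        ids=np.array(iids, dtype=object),
        diseased=np.array(dis, dtype=bool),
        coords=np.array(coords, dtype=float),
        weights=np.array(weights, dtype=float) if weights is not None else None,
        fids=np.array(fids, dtype=object),
    )


def _read_combined(path: str | Path) -> Cohort:
    rows = _read_table(path)
    lineno0, header = rows[0]
    cols = [h.upper().lstrip("#") for h in header]
    required = ["FID", "IID", "PHENOTYPE"]
    for r in required:
        if r not in cols:
            raise ValueError(f"{path}:{lineno0}: combined TSV header must include {r}")
    pc_cols = [i for i, h in enumerate(cols) if h.startswith("PC")]
    if not pc_cols:
        raise ValueError(f"{path}:{lineno0}: no PC columns in header")
    i_fid, i_iid, i_ph = (cols.index(r) for r in required)
    i_w = cols.index("WEIGHT") if "WEIGHT" in cols else None
    fids, iids, dis, coords, weights = [], [], [], [], []
    n_missing = 0
    for lineno, toks in rows[1:]:
        if len(toks) != len(cols):
            raise ValueError(f"{path}:{lineno}: expected {len(cols)} fields, got {len(toks)}")
        ph = _pheno_from_code(toks[i_ph], str(path), lineno)
        if ph is None:
            n_missing += 1
            continue
        fids.append(toks[i_fid])
        iids.append(toks[i_iid])
        dis.append(ph)
        coords.append([_parse_float(toks[i], str(path), lineno, "PC") for i in pc_cols])
        if i_w is not None:
            weights.append(_parse_float(toks[i_w], str(path), lineno, "WEIGHT"))
    return _finalize(fids, iids, dis, coords, weights if i_w is not None else None, n_missing, str(path))


def _read_pair(eigenvec: str | Path, pheno: str | Path) -> Cohort:
    pheno_map: dict[tuple[str, str], bool | None] = {}
    rows = _read_table(pheno)
    start = 1 if rows[0][1][0].lstrip("#").upper() == "FID" else 0
    for lineno, toks in rows[start:]:
        if len(toks) < 3:
            raise ValueError(f"{pheno}:{lineno}: expected FID IID PHENO")
        key = (toks[0], toks[1])
        if key in pheno_map:
            raise ValueError(f"{pheno}:{lineno}: duplicate subject {key}")
        pheno_map[key] = _pheno_from_code(toks[2], str(pheno), lineno)
    fids, iids, dis, coords = [], [], [], []
    n_missing, seen = 0, set()
    for lineno, fid, iid, pcs in _eigenvec_rows(eigenvec):
        key = (fid, iid)
        if key in seen:
            raise ValueError(f"{eigenvec}:{lineno}: duplicate subject {key}")
        seen.add(key)
        if key not in pheno_map:
            raise ValueError(f"{eigenvec}:{lineno}: subject {key} missing from phenotype file")
        ph = pheno_map[key]
        if ph is None:
            n_missing += 1
            continue
        fids.append(fid)
        iids.append(iid)
        dis.append(ph)
        coords.append(pcs)
    extra = set(pheno_map) - seen
    if extra:
        raise ValueError(f"{pheno}: subjects {sorted(extra)[:3]}... absent from eigenvec file")
    return _finalize(fids, iids, dis, coords, None, n_missing, str(eigenvec))


def write_weights(
    result: HomogenizationResult | np.ndarray, cohort: Cohort, path: str | Path
) -> None:
    """Write a ``FID IID WEIGHT`` TSV at full precision, in cohort order."""
    weights = result.final_weights if isinstance(result, HomogenizationResult) else np.asarray(result)
    with open(path, "w") as fh:
        fh.write("FID\tIID\tWEIGHT\n")
        for fid, iid, w in zip(cohort.fids, cohort.ids, weights):
            fh.write(f"{fid}\t{iid}\t{float(w)!r}\n")


def read_weights(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a ``FID IID WEIGHT`` TSV into a {(FID, IID): weight} map."""
    rows = _read_table(path)
    start = 1 if rows[0][1][0].lstrip("#").upper() == "FID" else 0
    out: dict[tuple[str, str], float] = {}
    for lineno, toks in rows[start:]:
        if len(toks) != 3:
            raise ValueError(f"{path}:{lineno}: expected FID IID WEIGHT")
        key = (toks[0], toks[1])
        if key in out:
            raise ValueError(f"{path}:{lineno}: duplicate subject {key}")
        out[key] = _parse_float(toks[2], str(path), lineno, "WEIGHT")
    return out


def apply_weights(cohort: Cohort, weights: dict[tuple[str, str], float]) -> Cohort:
    """Return a copy of the cohort carrying the given per-subject weights."""
    out = cohort.copy()
    for i, key in enumerate(zip(cohort.fids, cohort.ids)):
        if key not in weights:
            raise ValueError(f"no weight for subject {key}")
        out.weights[i] = weights[key]
    return out


def write_eigenvec(proj: PCProjection, path: str | Path, fids: list[str] | None = None) -> None:
    """Write a PLINK .eigenvec-style whitespace table FID IID PC1..PCk."""
    fids = fids if fids is not None else proj.subjects
    with open(path, "w") as fh:
        for fid, iid, row in zip(fids, proj.subjects, proj.coords):
            fh.write(" ".join([str(fid), str(iid)] + [repr(float(v)) for v in row]) + "\n")


def read_raw(path: str | Path) -> GenotypeMatrix:
    """Read a PLINK .raw-style additive genotype text matrix.

    Header: FID IID PAT MAT SEX PHENOTYPE SNP1 SNP2 ...; dosages in
    {0, 1, 2} with NA for missing.
    """
    rows = _read_table(path)
    lineno0, header = rows[0]
    if len(header) < 7 or header[0].upper() != "FID":
        raise ValueError(f"{path}:{lineno0}: not a .raw header (expect FID IID ... SNPs)")
    snps = header[6:]
    subjects, fids, calls = [], [], []
    for lineno, toks in rows[1:]:
        if len(toks) != len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(toks)}")
        fids.append(toks[0])
        subjects.append(toks[1])
        row = []
        for t in toks[6:]:
            if t.upper() == "NA":
                row.append(np.nan)
            else:
                v = _parse_float(t, str(path), lineno, "dosage")
                if v not in (0.0, 1.0, 2.0):
                    raise ValueError(f"{path}:{lineno}: dosage {t!r} not in {{0,1,2,NA}}")
                row.append(v)
        calls.append(row)
    return GenotypeMatrix(subjects=subjects, snps=snps, dosages=np.array(calls), fids=fids)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into an additive dosage matrix (ALT-allele counts)."""
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snps, cols = [], []
    for var in vcf:
        snps.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        gts = var.genotype.array()[:, :2]
        dose = np.where((gts < 0).any(axis=1), np.nan, (gts > 0).sum(axis=1).astype(float))
        cols.append(dose)
    if not cols:
        raise ValueError(f"{path}: no variants")
    return GenotypeMatrix(subjects=subjects, snps=snps, dosages=np.column_stack(cols))
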