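"""Readers and writers for every on-disk artifact.

Canonical interchange dialects (all plain text, tab-separated):

* genotype TSV — header ``sample_id<TAB>marker_1...marker_L``, body cells in
  {0, 1, 2, NA};
* frequency TSV — long format ``marker_id, population, alt_freq,
  n_chromosomes``, complete over the population x marker grid;
* pedigree TSV — ``family_id, sample_id, mother_id, father_id, role`` with
  ``0`` marking an absent parent;
* panel file — one marker id per line, ``#`` comments allowed;
* results — JSON with a ``schema_version`` field.

VCF ingestion (biallelic, GT only) is a convenience on top of cyvcf2.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, MarkerPanel, PedigreeTable, ReferenceFrequencies

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_frequencies",
    "write_frequencies",
    "read_pedigree",
    "write_pedigree",
    "read_panel",
    "write_panel",
    "write_results",
    "read_results",
]

RESULTS_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from TSV (canonical) or biallelic VCF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_genotypes_tsv(path)
    if dialect == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'vcf'")


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if not cols or cols[0] != "sample_id":
            raise ValueError(f"{path}: first header column must be 'sample_id'")
        marker_ids = cols[1:]
        sample_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(cols):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(cols)} columns, got {len(cells)}"
                )
            sample_ids.append(cells[0])
            row = []
            for j, cell in enumerate(cells[1:], start=2):
                if cell == "NA":
                    row.append(np.nan)
                elif cell in ("0", "1", "2"):
                    row.append(float(cell))
                else:
                    raise ValueError(
                        f"{path}:{lineno}: column {j} ({marker_ids[j - 2]}): "
                        f"invalid genotype cell {cell!r}"
                    )
            rows.append(row)
    dosages = np.array(rows, dtype=float).reshape(len(sample_ids), len(marker_ids))
    return GenotypeMatrix(sample_ids, marker_ids, dosages)


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF ingestion requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic record at {variant.CHROM}:{variant.POS}"
            )
        marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        col = np.full(len(sample_ids), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a != -1]
            if len(alleles) == 2:
                col[i] = float(sum(alleles))
        columns.append(col)
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    )
    return GenotypeMatrix(sample_ids, marker_ids, dosages)


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write the canonical genotype TSV (missing as ``NA``)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(g.marker_ids) + "\n" if g.marker_ids
                 else "sample_id\n")
        for i, sample in enumerate(g.sample_ids):
            cells = [
                "NA" if np.isnan(v) else str(int(v)) for v in g.dosages[i]
            ]
            fh.write("\t".join([sample] + cells) + "\n")


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def read_frequencies(path) -> ReferenceFrequencies:
    """Read a long-format frequency TSV; the population x marker grid must be complete."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"marker_id": str, "population": str},
        float_precision="round_trip",
    )
    required = {"marker_id", "population", "alt_freq", "n_chromosomes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["alt_freq"] = pd.to_numeric(df["alt_freq"], errors="raise")
    df["n_chromosomes"] = pd.to_numeric(df["n_chromosomes"], errors="raise")
    bad = df[(df["alt_freq"] < 0) | (df["alt_freq"] > 1)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"{path}: alt_freq {row['alt_freq']!r} out of [0, 1] "
            f"({row['population']}/{row['marker_id']})"
        )
    populations = list(dict.fromkeys(df["population"]))
    marker_ids = list(dict.fromkeys(df["marker_id"]))
    pivot_p = df.pivot(index="population", columns="marker_id", values="alt_freq")
    pivot_n = df.pivot(index="population", columns="marker_id", values="n_chromosomes")
    if pivot_p.isna().any().any():
        raise ValueError(f"{path}: incomplete population x marker grid")
    p = pivot_p.loc[populations, marker_ids].to_numpy(dtype=float)
    n = pivot_n.loc[populations, marker_ids].to_numpy(dtype=float)
    return ReferenceFrequencies(populations, marker_ids, p, n)


def write_frequencies(f: ReferenceFrequencies, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("marker_id\tpopulation\talt_freq\tn_chromosomes\n")
        for i, pop in enumerate(f.populations):
            for j, marker in enumerate(f.marker_ids):
                fh.write(
                    f"{marker}\t{pop}\t{float(f.alt_freq[i, j])!r}\t{int(f.n_chrom[i, j])}\n"
                )


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

def read_pedigree(path) -> PedigreeTable:
    """Read a pedigree TSV (``0`` = absent parent; founders have both absent)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "sample_id", "mother_id", "father_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.replace({"mother_id": {"0": None}, "father_id": {"0": None}})
    for _, row in df.iterrows():
        if row["role"] == "offspring" and (
            row["mother_id"] is None or row["father_id"] is None
        ):
            raise ValueError(
                f"{path}: offspring {row['sample_id']!r} has an absent parent"
            )
    return PedigreeTable(df)


def write_pedigree(ped: PedigreeTable, path) -> None:
    df = ped.df.copy()
    df["mother_id"] = df["mother_id"].map(lambda v: "0" if v is None else v)
    df["father_id"] = df["father_id"].map(lambda v: "0" if v is None else v)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

def read_panel(path, panel_id: str | None = None) -> MarkerPanel:
    """Read a panel file: one marker id per line, ``#`` comments allowed."""
    path = Path(path)
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    return MarkerPanel(panel_id or path.stem, ids)


def write_panel(panel: MarkerPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# panel {panel.panel_id} ({len(panel)} markers)\n")
        for m in panel.marker_ids:
            fh.write(m + "\n")


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def write_results(obj: dict, path) -> None:
    """Serialize a result mapping to JSON with a schema version field."""
    payload = {"schema_version": RESULTS_SCHEMA_VERSION}
    payload.update(obj)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def read_results(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
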