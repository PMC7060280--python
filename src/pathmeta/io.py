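"""Readers and writers for the pipeline's plain-text formats.

All formats are tab-separated text: expression matrices (first column
gene id, header row of sample ids), phenotype tables (sample_id, group),
pathway edge lists (pathway_id, pathway_name, source_gene, target_gene,
interaction), GMT gene-set files for enrichment-only use, and the result
tables.  Round trips are lossless at full float precision.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .effect_size import CASE, CONTROL, StudyData
from .impact import PathwayGraph

__all__ = [
    "read_expression",
    "read_phenotype",
    "read_study",
    "read_studies_dir",
    "read_pathways",
    "read_gmt",
    "write_gmt",
    "write_table",
    "read_table",
]

_INTERACTION_TOKENS = {
    "activation": 1.0,
    "+1": 1.0,
    "1": 1.0,
    "repression": -1.0,
    "-1": -1.0,
}

_FLOAT_FMT = "%.17g"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (gene ids in column one)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicate gene ids {list(dupes)[:5]}")
    return df


def read_phenotype(
    path: str | Path,
    case_label: str = CASE,
    control_label: str = CONTROL,
) -> pd.Series:
    """Read a phenotype TSV (columns sample_id, group) to a case/control map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: phenotype file needs columns {sorted(required)}")
    mapping = {case_label: CASE, control_label: CONTROL}
    bad = sorted(set(df["group"]) - set(mapping))
    if bad:
        raise ValueError(
            f"{path}: unknown group labels {bad}; expected "
            f"{case_label!r} or {control_label!r}"
        )
    return pd.Series(
        df["group"].map(mapping).to_numpy(), index=df["sample_id"], name="group"
    )


def read_study(
    expression_path: str | Path,
    phenotype_path: str | Path,
    study_id: str | None = None,
    case_label: str = CASE,
    control_label: str = CONTROL,
) -> StudyData:
    """Read one study; phenotype must cover every expression sample."""
    matrix = read_expression(expression_path)
    groups = read_phenotype(phenotype_path, case_label, control_label)
    if study_id is None:
        study_id = Path(expression_path).stem.removesuffix("_expression")
    return StudyData(study_id, matrix, groups)


def read_studies_dir(
    directory: str | Path,
    case_label: str = CASE,
    control_label: str = CONTROL,
) -> list[StudyData]:
    """Read every study in a directory.

    Expects paired files ``<study>_expression.tsv`` and
    ``<study>_phenotype.tsv``.
    """
    directory = Path(directory)
    studies = []
    for expr in sorted(directory.glob("*_expression.tsv")):
        stem = expr.name.removesuffix("_expression.tsv")
        pheno = directory / f"{stem}_phenotype.tsv"
        if not pheno.exists():
            raise FileNotFoundError(f"missing phenotype file for study {stem!r}")
        studies.append(read_study(expr, pheno, stem, case_label, control_label))
    if not studies:
        raise FileNotFoundError(f"no *_expression.tsv files in {directory}")
    return studies


def write_study(study: StudyData, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study.matrix.to_csv(
        directory / f"{study.study_id}_expression.tsv", sep="\t",
        index_label="gene", float_format=_FLOAT_FMT,
    )
    pheno = pd.DataFrame(
        {"sample_id": study.groups.index, "group": study.groups.to_numpy()}
    )
    pheno.to_csv(directory / f"{study.study_id}_phenotype.tsv", sep="\t", index=False)


def read_pathways(path: str | Path) -> list[PathwayGraph]:
    """Read a pathway edge-list TSV into signed directed graphs.

    Columns: pathway_id, pathway_name, source_gene, target_gene,
    interaction (``activation``/``+1`` or ``repression``/``-1``).
    Malformed lines are reported with their line number.
    """
    by_id: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["pathway_id", "pathway_name", "source_gene",
                    "target_gene", "interaction"]
        if header != expected:
            raise ValueError(f"{path}:1: header must be {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pid, name, src, tgt, token = fields
            if token not in _INTERACTION_TOKENS:
                raise ValueError(
                    f"{path}:{lineno}: unknown interaction token {token!r}"
                )
            rec = by_id.setdefault(pid, {"name": name, "nodes": [], "edges": []})
            rec["nodes"].extend((src, tgt))
            rec["edges"].append((src, tgt, _INTERACTION_TOKENS[token]))
    if not by_id:
        raise ValueError(f"{path}: pathway file contains no edges")
    return [
        PathwayGraph(pid, rec["name"], rec["nodes"], rec["edges"])
        for pid, rec in by_id.items()
    ]


def write_pathways(pathways: list[PathwayGraph], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_id\tpathway_name\tsource_gene\ttarget_gene\tinteraction\n")
        for g in pathways:
            for u, v, beta in g.edges:
                token = "activation" if beta > 0 else "repression"
                fh.write(f"{g.pathway_id}\t{g.name}\t{u}\t{v}\t{token}\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file: pathway id -> (description, gene list)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need id, description, >= 1 gene"
                )
            sets[fields[0]] = (fields[1], fields[2:])
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, (desc, genes) in sets.items():
            fh.write("\t".join([pid, desc, *genes]) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a results table as TSV at full float precision."""
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col,
                       float_precision="round_trip")
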