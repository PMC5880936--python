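"""Readers, writers and the end-to-end report bundle.

File conventions: CSV for chemistry endpoint tables (human-edited), TSV
with a ``#OTU_ID`` first column for OTU tables (QIIME-legacy), newick with
branch lengths for trees; UTF-8, decimal point.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import __version__
from .budget import (
    IncubationEndpoint,
    TreatmentLabel,
    compute_ledgers,
    ledgers_to_frame,
    summarize_groups,
)
from .community import (
    OtuTable,
    aggregate_taxa,
    alpha_diversity,
    associate,
    generalized_unifrac,
    nmds,
    permanova,
)
from .stoichiometry import BottleGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "read_endpoints",
    "write_endpoints",
    "endpoints_from_frame",
    "read_otu_table",
    "write_otu_table",
    "read_tree",
    "write_tree",
    "RunConfig",
    "report",
]

MANDATORY_COLUMNS = [
    "group", "amendment", "replicate",
    "fe2_mg_g", "sulfate_mg_g", "ch4_permil",
    "pcp_ug_g", "tecp_ug_g", "tcp_ug_g", "dcp_ug_g",
]
OPTIONAL_COLUMNS = [
    "nitrate_mg_g", "co2_permil", "ph", "eh_mv", "doc_mg_kg", "don_mg_kg",
]
_NONNEGATIVE = [
    "fe2_mg_g", "sulfate_mg_g", "nitrate_mg_g", "ch4_permil", "co2_permil",
    "pcp_ug_g", "tecp_ug_g", "tcp_ug_g", "dcp_ug_g",
]


class SchemaError(ValueError):
    """Endpoint file does not conform to the documented schema."""


def read_endpoints(path: str | Path) -> list[IncubationEndpoint]:
    """Read and validate an endpoint CSV into typed rows.

    Raises :class:`SchemaError` for missing mandatory columns; row-level
    violations (negative concentrations, CH4 outside [0, 1000] permil) are
    reported with their line numbers.  Unknown extra columns are accepted
    with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    extra = [
        c for c in df.columns if c not in MANDATORY_COLUMNS + OPTIONAL_COLUMNS
    ]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, extra)
    errors = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        for col in _NONNEGATIVE:
            if col in df.columns and pd.notna(row[col]) and row[col] < 0:
                errors.append(f"line {line}: negative {col} ({row[col]})")
        if pd.notna(row["ch4_permil"]) and not 0 <= row["ch4_permil"] <= 1000:
            errors.append(
                f"line {line}: ch4_permil out of [0, 1000] ({row['ch4_permil']})"
            )
    if errors:
        raise SchemaError(f"{path}: " + "; ".join(errors))
    return endpoints_from_frame(df)


def endpoints_from_frame(df: pd.DataFrame) -> list[IncubationEndpoint]:
    """Convert a tidy endpoint DataFrame to typed rows."""

    def opt(row, col):
        if col in row.index and pd.notna(row[col]):
            return float(row[col])
        return None

    out = []
    for _, row in df.iterrows():
        out.append(
            IncubationEndpoint(
                label=TreatmentLabel(
                    str(row["group"]), str(row["amendment"]), int(row["replicate"])
                ),
                fe2=float(row["fe2_mg_g"]),
                sulfate=float(row["sulfate_mg_g"]),
                ch4=float(row["ch4_permil"]),
                pcp=float(row["pcp_ug_g"]),
                tecp=float(row["tecp_ug_g"]),
                tcp=float(row["tcp_ug_g"]),
                dcp=float(row["dcp_ug_g"]),
                nitrate=opt(row, "nitrate_mg_g"),
                co2=opt(row, "co2_permil"),
                ph=opt(row, "ph"),
                eh=opt(row, "eh_mv"),
                doc=opt(row, "doc_mg_kg"),
                don=opt(row, "don_mg_kg"),
            )
        )
    return out


def write_endpoints(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_otu_table(path: str | Path) -> OtuTable:
    """Read a legacy-style OTU TSV (first column ``#OTU_ID``, optional last
    column ``taxonomy`` with semicolon-ranked lineages)."""
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    if first.lstrip("#").strip().upper() not in ("OTU_ID", "OTU ID", "OTUID"):
        raise SchemaError(f"{path}: first column must be '#OTU_ID', got {first!r}")
    df = df.set_index(first)
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df["taxonomy"].astype(str).to_dict()
        df = df.drop(columns=["taxonomy"])
    return OtuTable(
        otu_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        counts=df.to_numpy(),
        taxonomy=taxonomy,
    )


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    df = table.to_frame()
    df.index.name = "#OTU_ID"
    if table.taxonomy is not None:
        df = df.assign(taxonomy=[table.taxonomy.get(o, "") for o in table.otu_ids])
    df.to_csv(path, sep="\t")


def read_tree(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


@dataclass
class RunConfig:
    """End-to-end analysis configuration for :func:`report`."""

    endpoints_path: str | Path
    otu_table_path: str | Path | None = None
    tree_path: str | Path | None = None
    output_dir: str | Path = "soilredox_report"
    geometry: BottleGeometry = field(default_factory=BottleGeometry)
    baseline: str = "matched"
    gunifrac_alpha: float = 0.5
    nmds_axes: int = 4
    permutations: int = 999
    taxa_rank: str = "family"
    dominance_threshold: float = 0.02
    association_threshold: float = 0.01
    permanova_factor: str = "group"
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.endpoints_path).exists():
            raise FileNotFoundError(self.endpoints_path)
        for p in (self.otu_table_path, self.tree_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not 0 <= self.gunifrac_alpha <= 1:
            raise ValueError("gunifrac_alpha must lie in [0, 1]")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")


def report(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and write the report bundle.

    Always produced: ``ledgers.csv``, ``group_summary.csv`` and
    ``run_log.json``.  When an OTU table (and tree) are configured, also
    ``alpha.csv``, ``gunifrac.tsv``, ``nmds.csv``, ``permanova.txt`` and
    ``associations.csv``.  Returns the mapping of artefact name to path.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    endpoints = read_endpoints(config.endpoints_path)
    ledgers = compute_ledgers(endpoints, config.geometry, config.baseline)
    ldf = ledgers_to_frame(ledgers)
    p = out / "ledgers.csv"
    ldf.to_csv(p, index=False)
    written["ledgers"] = p

    summary = summarize_groups(ldf)
    p = out / "group_summary.csv"
    summary.to_csv(p, index=False)
    written["group_summary"] = p

    if config.otu_table_path is not None:
        table = read_otu_table(config.otu_table_path)
        adiv = alpha_diversity(table)
        p = out / "alpha.csv"
        adiv.rename_axis("sample_id").to_csv(p)
        written["alpha"] = p

        if config.tree_path is None:
            raise FileNotFoundError(
                "an OTU table was given but no tree; generalized UniFrac "
                "requires a rooted newick tree (set tree_path)"
            )
        tree = read_tree(config.tree_path)
        dm = generalized_unifrac(table, tree, config.gunifrac_alpha)
        p = out / "gunifrac.tsv"
        dm.to_data_frame().rename_axis("sample_id").to_csv(p, sep="\t")
        written["gunifrac"] = p

        res = nmds(dm, k=config.nmds_axes, seed=config.seed)
        p = out / "nmds.csv"
        coords = res.coordinates.copy()
        coords["stress"] = res.stress
        coords.rename_axis("sample_id").to_csv(p)
        written["nmds"] = p

        # factor defaults to molybdate condition: parse from sample ids
        groups = [sid.split(".")[0] for sid in table.sample_ids]
        perma = permanova(
            dm, groups, permutations=config.permutations, seed=config.seed,
            factor=config.permanova_factor,
        )
        p = out / "permanova.txt"
        p.write_text(
            f"factor\t{perma.factor}\n"
            f"pseudo_F\t{perma.pseudo_F:.6g}\n"
            f"p_value\t{perma.p_value:.6g}\n"
            f"permutations\t{perma.permutations}\n"
        )
        written["permanova"] = p

        if table.taxonomy is not None:
            taxa = aggregate_taxa(
                table, config.taxa_rank, config.association_threshold
            ).drop(index="other", errors="ignore")
            env = pd.DataFrame(
                {
                    "fe2_mg_g": [e.fe2 for e in endpoints],
                    "sulfate_mg_g": [e.sulfate for e in endpoints],
                    "ch4_permil": [e.ch4 for e in endpoints],
                    "pcp_ug_g": [e.pcp for e in endpoints],
                },
                index=[
                    f"{e.label.group}.{e.label.amendment}.{e.label.replicate}"
                    for e in endpoints
                ],
            )
            shared = [s for s in taxa.columns if s in env.index]
            if len(shared) >= 4:
                assoc = associate(taxa, env)
                p = out / "associations.csv"
                assoc.to_csv(p, index=False)
                written["associations"] = p

    log = {
        "soilredox_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": {
            k: str(v) for k, v in asdict(config).items()
        },
        "outputs": {k: str(v) for k, v in written.items()},
    }
    p = out / "run_log.json"
    p.write_text(json.dumps(log, indent=2))
    written["run_log"] = p
    return written
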