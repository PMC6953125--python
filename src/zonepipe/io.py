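"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is TSV, GMT, MTX or YAML so intermediate stages can be
inspected or swapped against external tools.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .zonation import GeneSet, LayeredCellMatrix

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_layer_probs",
    "write_layer_probs",
    "read_design",
    "write_design",
    "read_alias_table",
    "read_footprint_model",
    "read_regulons",
    "read_signature",
    "write_signature",
    "read_config",
    "write_config",
]


def read_gmt(path: str | Path, direction: str = "untagged") -> list[GeneSet]:
    """Parse a GMT file: name <TAB> description <TAB> member genes..."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need >= 3 fields): {line[:60]!r}")
        name, _desc, *genes = fields
        sets.append(GeneSet(name=name, members=frozenset(g for g in genes if g),
                            direction=direction))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    lines = []
    for s in sets:
        lines.append("\t".join([s.name, s.direction] + sorted(s.members)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples/cells counts with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(counts: np.ndarray, gene_ids, col_ids, path: str | Path) -> None:
    pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"), columns=col_ids).to_csv(
        path, sep="\t"
    )


def write_counts_mtx(counts: np.ndarray, gene_ids, col_ids, prefix: str | Path) -> None:
    """MatrixMarket triple: <prefix>.mtx, <prefix>.genes.tsv, <prefix>.cells.tsv."""
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    prefix = Path(prefix)
    mmwrite(str(prefix) + ".mtx", coo_matrix(np.asarray(counts)))
    Path(str(prefix) + ".genes.tsv").write_text("\n".join(gene_ids) + "\n")
    Path(str(prefix) + ".cells.tsv").write_text("\n".join(col_ids) + "\n")


def read_counts_mtx(prefix: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    from scipy.io import mmread

    prefix = Path(prefix)
    counts = np.asarray(mmread(str(prefix) + ".mtx").todense())
    genes = Path(str(prefix) + ".genes.tsv").read_text().split()
    cells = Path(str(prefix) + ".cells.tsv").read_text().split()
    return counts, genes, cells


def write_layer_probs(probs: np.ndarray, cell_ids, path: str | Path) -> None:
    cols = [f"layer{i + 1}" for i in range(probs.shape[1])]
    pd.DataFrame(probs, index=pd.Index(cell_ids, name="cell"), columns=cols).to_csv(
        path, sep="\t"
    )


def read_layer_probs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t")


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", index_col=0)
    required = {"treatment", "month", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    design["month"] = design["month"].astype(int)
    return design


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV old_symbol <TAB> current_symbol."""
    table = pd.read_csv(path, sep="\t", header=None, names=["old", "new"], dtype=str)
    if table["old"].duplicated().any():
        dupes = table.loc[table["old"].duplicated(), "old"].tolist()[:5]
        raise ValueError(f"alias table maps a symbol twice: {dupes}")
    return dict(zip(table["old"], table["new"]))


def read_footprint_model(path: str | Path) -> dict[str, dict[str, float]]:
    """Long-format TSV with columns pathway, gene, weight."""
    table = pd.read_csv(path, sep="\t")
    model: dict[str, dict[str, float]] = {}
    for row in table.itertuples(index=False):
        if row.weight != 0:
            model.setdefault(row.pathway, {})[row.gene] = float(row.weight)
    return model


def read_regulons(path: str | Path) -> dict[str, dict[str, int]]:
    """TSV with columns tf, target, mode (+1 activation, -1 repression)."""
    table = pd.read_csv(path, sep="\t")
    regulons: dict[str, dict[str, int]] = {}
    for row in table.itertuples(index=False):
        mode = int(row.mode)
        if mode not in (-1, 1):
            raise ValueError(f"regulon mode must be +1 or -1, got {mode}")
        regulons.setdefault(row.tf, {})[row.target] = mode
    return regulons


def read_signature(path: str | Path) -> pd.Series:
    """Two-column TSV gene <TAB> statistic, returned sorted descending."""
    from .enrichment import rank_signature

    table = pd.read_csv(path, sep="\t", index_col=0)
    return rank_signature(table.iloc[:, 0])


def write_signature(signature: pd.Series, path: str | Path) -> None:
    signature.rename("statistic").to_csv(path, sep="\t")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a YAML mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
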