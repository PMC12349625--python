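"""End-to-end analysis orchestration and report rendering.

``run_analysis`` takes a genotype file and writes the full report
bundle: the per-population diversity table, percent-polymorphic-loci
table, per-locus F-statistics table, Nei unbiased distance matrix,
UPGMA tree (Newick + merge table) and a machine-readable
``summary.json``.  Tables are written at full precision; a ``display/``
subdirectory holds copies rounded half-away-from-zero to the configured
number of decimals (3 by default, matching the usual journal-table
rendering).  Undefined cells are written as ``NA`` and infinite
distances as ``inf``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, asdict
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import __version__
from .genotypes import GenotypeMatrix, read_genalex, read_long_tsv, write_genalex, write_long_tsv
from .diversity import PopSummary, grand_means, population_summary
from .fstats import fstats_table
from .distance import distance_matrix
from .simulate import SimConfig, simulate
from .upgma import cluster_membership, to_newick, upgma

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_analysis", "run_simulate", "round_half_away"]


def round_half_away(x: float | None, digits: int = 3) -> float | None:
    """Round half away from zero (0.0005 -> 0.001, -0.0005 -> -0.001)."""
    if x is None or not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run."""

    genotypes: str
    format: str = "genalex"
    out: str = "results"
    digits: int = 3
    k: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.format not in ("genalex", "long"):
            raise ValueError(f"unknown format {self.format!r}; use 'genalex' or 'long'")
        if self.digits < 0:
            raise ValueError("digits must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _fmt(x: float | None) -> object:
    if x is None:
        return "NA"
    if math.isinf(x):
        return "inf"
    return x


def _diversity_frame(summaries: list[PopSummary], mean_row: PopSummary) -> pd.DataFrame:
    rows = []
    for s in [*summaries, mean_row]:
        rows.append(
            {
                "Population": s.population,
                "N": s.n,
                "Na": s.na,
                "Ne": s.ne,
                "I": s.i,
                "Ho": s.ho,
                "He": s.he,
                "uHe": s.uhe,
                "F": _fmt(s.f),
            }
        )
    return pd.DataFrame(rows)


def _round_frame(df: pd.DataFrame, digits: int) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        out[col] = [
            round_half_away(v, digits) if isinstance(v, float) else v for v in out[col]
        ]
    return out


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_analysis(config: RunConfig) -> dict:
    """Run the whole pipeline and write the report bundle; returns the objects."""
    config.validate()
    reader = read_genalex if config.format == "genalex" else read_long_tsv
    g: GenotypeMatrix = reader(config.genotypes)  # read before writing anything

    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    display = outdir / "display"
    display.mkdir(exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    pkg_logger = logging.getLogger("ssrpopgen")
    old_level = pkg_logger.level
    pkg_logger.addHandler(handler)
    pkg_logger.setLevel(config.log_level.upper())
    try:
        logger.info(
            "ssrpopgen %s: gene-diversity F-statistics (Nei 1977, unweighted population "
            "means), Nei 1978 unbiased distance, UPGMA average linkage", __version__,
        )
        logger.info("input: %s (%s), %r", config.genotypes, config.format, g)

        logger.info("stage: diversity statistics")
        summaries = [population_summary(g, p) for p in g.populations]
        mean_row = grand_means(summaries)
        div_df = _diversity_frame(summaries, mean_row)
        pctp_df = pd.DataFrame(
            {"Population": [s.population for s in summaries],
             "pctP": [s.pct_polymorphic for s in summaries]}
        )

        logger.info("stage: F-statistics")
        ftab = fstats_table(g)
        f_rows = [
            {"Locus": r.locus, "Fis": _fmt(r.fis), "Fit": _fmt(r.fit),
             "Fst": _fmt(r.fst), "Nm": _fmt(r.nm)}
            for r in ftab.rows
        ]
        f_rows.append({"Locus": "Mean", **{c.capitalize() if c != "nm" else "Nm": _fmt(ftab.mean[c]) for c in ("fis", "fit", "fst", "nm")}})
        f_rows.append({"Locus": "SE", **{c.capitalize() if c != "nm" else "Nm": _fmt(ftab.se[c]) for c in ("fis", "fit", "fst", "nm")}})
        f_df = pd.DataFrame(f_rows)

        logger.info("stage: Nei unbiased distance matrix")
        dm = distance_matrix(g)
        dist_df = pd.DataFrame(dm.values, index=list(dm.labels), columns=list(dm.labels))

        logger.info("stage: UPGMA clustering")
        tree = upgma(dm.with_inf_sentinel())
        newick = to_newick(tree)
        members = tree.node_members()
        merge_rows = []
        for m, (left, right, height) in enumerate(tree.merges):
            merge_rows.append(
                {
                    "merge": m + 1,
                    "left": "+".join(tree.leaves[i] for i in sorted(members[left])),
                    "right": "+".join(tree.leaves[i] for i in sorted(members[right])),
                    "height": height,
                }
            )
        merges_df = pd.DataFrame(merge_rows)
        clusters = cluster_membership(tree, min(config.k, len(tree.leaves)))

        logger.info("stage: writing report bundle to %s", outdir)
        _write_tsv(div_df, outdir / "diversity_table.tsv")
        _write_tsv(pctp_df, outdir / "pctP.tsv")
        _write_tsv(f_df, outdir / "fstats_table.tsv")
        dist_df.to_csv(outdir / "nei_distance.tsv", sep="\t")
        (outdir / "tree.nwk").write_text(newick + "\n", encoding="utf-8")
        _write_tsv(merges_df, outdir / "merges.tsv")

        for df, name in ((div_df, "diversity_table.tsv"), (pctp_df, "pctP.tsv"),
                         (f_df, "fstats_table.tsv")):
            _write_tsv(_round_frame(df, config.digits), display / name)
        _round_frame(dist_df, config.digits).to_csv(display / "nei_distance.tsv", sep="\t")

        summary = {
            "config": asdict(config),
            "n_individuals": g.n_individuals,
            "n_loci": g.n_loci,
            "populations": list(g.populations),
            "grand_means": {
                "N": mean_row.n, "Na": mean_row.na, "Ne": mean_row.ne, "I": mean_row.i,
                "Ho": mean_row.ho, "He": mean_row.he, "uHe": mean_row.uhe,
                "F": mean_row.f, "pctP": mean_row.pct_polymorphic,
            },
            "fstat_means": ftab.mean,
            "fstat_se": ftab.se,
            "clusters_at_k": clusters,
            "newick": newick,
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, allow_nan=True), encoding="utf-8"
        )
        (outdir / "config.json").write_text(
            json.dumps(asdict(config), indent=2), encoding="utf-8"
        )
    finally:
        pkg_logger.removeHandler(handler)
        pkg_logger.setLevel(old_level)
        handler.close()

    return {
        "matrix": g,
        "summaries": summaries,
        "grand_means": mean_row,
        "fstats": ftab,
        "distances": dm,
        "tree": tree,
        "clusters": clusters,
        "newick": newick,
        "outdir": outdir,
    }


def run_simulate(config: SimConfig, out) -> dict:
    """Simulate a dataset and write it as GenAlEx CSV + long TSV + config echo."""
    config.validate()  # fail before any file is written
    g = simulate(config)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "genotypes.csv"
    tsv_path = outdir / "genotypes.tsv"
    write_genalex(g, csv_path, title=f"ssrpopgen simulation seed={config.seed}")
    write_long_tsv(g, tsv_path)
    (outdir / "sim_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2), encoding="utf-8"
    )
    return {"matrix": g, "genalex": csv_path, "long": tsv_path}
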