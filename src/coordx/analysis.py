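"""End-to-end analysis: regulatory-feature coupling model and results.

:class:`RegulatoryCoordination` is the model object: it holds the joined
per-gene table of regulatory features (promoter class, uAUG class, region
lengths, exon count) and measured expression (translation efficiency,
ribosomal density, Gro-seq rate, tissue summaries).  Calling :meth:`fit`
runs every comparison of the analysis — uAUG prevalence across promoter
classes, length/expression contrasts between uAUG and promoter groups,
rank correlations, and the top-vs-bottom expression split — and returns a
:class:`CoordinationResults` carrying, for every comparison, the group
sizes, test statistic, two-sided p-value, effect direction, significance
stars and boxplot summaries.

Gene universes differ by section, mirroring how the underlying data layers
differ: promoter-stratified sections use only genes with a promoter call;
translation sections only genes with defined TE (mRNA reads > 0) and a
non-zero CDS; Gro-seq sections only genes longer than 1 kb and above the
5 reads/kb background; tissue-level comparisons only genes whose mean
expression clears the 200-unit background (breadth uses all genes with
tissue data).  Every section records its n.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import expression_metrics as em
from . import genome_io, group_stats, utr_features
from .group_stats import TestResult, boxplot_summary
from .promoter_tata import MotifSpec, classify_cohort
from .synthetic_data import Cohort

__all__ = [
    "AnalysisConfig",
    "RegulatoryCoordination",
    "CoordinationResults",
    "run_analysis",
    "star_annotation",
]

LENGTH_FEATURES = ("utr5_length", "utr3_length", "cds_length", "gene_length")


def star_annotation(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else NS
    (strict inequalities, so p = 0.05 is NS)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the analysis, all overridable.

    ``groseq_background`` in reads/kb, ``tissue_threshold`` in atlas
    expression units, ``top_fractions`` the expression-split fractions.
    """

    motif: str = "TATAWAG"
    max_mismatch: int = 1
    groseq_background: float = em.GROSEQ_BACKGROUND
    tissue_threshold: float = em.TISSUE_THRESHOLD
    top_fractions: tuple[float, ...] = (0.25, 0.10)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _summary_dict(values: np.ndarray) -> dict[str, float]:
    s = boxplot_summary(values)
    return {
        "median": s.median,
        "q25": s.q25,
        "q75": s.q75,
        "whisker_low": s.whisker_low,
        "whisker_high": s.whisker_high,
        "n": s.n,
    }


def _test_dict(result: TestResult) -> dict[str, Any]:
    return {
        "test": result.test_name,
        "statistic": result.statistic,
        "p_value": result.p_value,
        "n_per_group": list(result.n_per_group),
        "direction": result.effect_direction,
        "stars": star_annotation(result.p_value),
    }


def _two_group(
    df: pd.DataFrame, value: str, group: str, order: tuple[str, str]
) -> dict[str, Any] | None:
    """MWU comparison of ``value`` between the two ``group`` levels in
    ``order`` (direction = sign of first-minus-second median)."""
    a = df.loc[df[group] == order[0], value].dropna().to_numpy(dtype=float)
    b = df.loc[df[group] == order[1], value].dropna().to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        return None
    res = group_stats.mann_whitney_u(a, b)
    out = _test_dict(res)
    out["groups"] = {
        order[0]: _summary_dict(a),
        order[1]: _summary_dict(b),
    }
    return out


class RegulatoryCoordination:
    """Model of coupled transcription/translation regulatory features.

    Parameters
    ----------
    data
        Per-gene table with at least the feature columns (``gene``,
        ``uaug_class``, the four lengths, ``exon_count``); expression
        columns (``te``, ``ribo_density``, ``mrna_reads``,
        ``groseq_rate``, ``tissue_*``) and ``tata_class`` are optional and
        gate the corresponding report sections.
    config
        Analysis thresholds; defaults match the standard pipeline.
    """

    def __init__(self, data: pd.DataFrame, config: AnalysisConfig | None = None) -> None:
        if "gene" not in data.columns or "uaug_class" not in data.columns:
            raise ValueError("data must carry 'gene' and 'uaug_class' columns")
        if data["gene"].duplicated().any():
            raise ValueError("duplicate gene ids in data")
        if len(data) == 0:
            raise ValueError("empty gene table: the join resolved no genes")
        self.data = data.reset_index(drop=True)
        self.config = config or AnalysisConfig()

    # ------------------------------------------------------------------ #
    @classmethod
    def from_tables(
        cls,
        features: pd.DataFrame,
        ribo: pd.DataFrame | None = None,
        groseq: pd.DataFrame | None = None,
        tissues: pd.DataFrame | None = None,
        config: AnalysisConfig | None = None,
    ) -> "RegulatoryCoordination":
        config = config or AnalysisConfig()
        data = em.build_expression_table(
            features,
            ribo=ribo,
            groseq=groseq,
            tissues=tissues,
            background_threshold=config.groseq_background,
            tissue_threshold=config.tissue_threshold,
        )
        return cls(data, config)

    @classmethod
    def from_cohort(
        cls, cohort: "Cohort | str | Path", config: AnalysisConfig | None = None
    ) -> "RegulatoryCoordination":
        """Build the model from a simulated cohort (in memory or on disk).

        Runs the genuine pipeline stages: promoter scanning of the window
        sequences, uAUG detection on the 5'UTRs, feature assembly and the
        expression joins — nothing is read from the cohort's truth table.
        """
        config = config or AnalysisConfig()
        motif = MotifSpec(pattern=config.motif, max_mismatch=config.max_mismatch)
        if isinstance(cohort, (str, Path)):
            d = Path(cohort)
            genes = genome_io.dedupe_by_symbol(genome_io.read_genepred(d / "refflat.tsv").genes)
            promoters = genome_io.read_fasta(d / "promoters.fa")
            regions = utr_features.build_regions(
                utr5=genome_io.read_fasta(d / "utr5.fa"),
                utr3=genome_io.read_fasta(d / "utr3.fa"),
                cds=genome_io.read_fasta(d / "cds.fa"),
            )
            ribo = (
                em.read_count_table(d / "ribo.tsv", ("gene", "footprint_reads", "mrna_reads"))
                if (d / "ribo.tsv").exists()
                else None
            )
            groseq = (
                em.read_count_table(d / "groseq.tsv", ("gene", "reads_beyond_1kb"))
                if (d / "groseq.tsv").exists()
                else None
            )
            tissues = (
                em.read_tissue_matrix(d / "tissues.tsv") if (d / "tissues.tsv").exists() else None
            )
        else:
            genes = genome_io.dedupe_by_symbol(cohort.genes)
            promoters = cohort.promoters
            regions = utr_features.build_regions(
                utr5=cohort.utr5, utr3=cohort.utr3, cds=cohort.cds
            )
            ribo, groseq, tissues = cohort.ribo, cohort.groseq, cohort.tissues
        calls, _ = classify_cohort(promoters, motif)
        features, _ = utr_features.build_feature_table(genes, regions, calls)
        return cls.from_tables(features, ribo=ribo, groseq=groseq, tissues=tissues, config=config)

    # ------------------------------------------------------------------ #
    def fit(self) -> "CoordinationResults":
        """Run every group comparison and correlation; assemble the report."""
        df = self.data
        sections: dict[str, Any] = {
            "universe": {
                "n_genes": int(len(df)),
                "n_with_promoter_call": int(df["tata_class"].notna().sum())
                if "tata_class" in df
                else 0,
            }
        }
        sections["uaug_prevalence"] = self._uaug_prevalence(df)
        sections["lengths_by_uaug"] = self._lengths_by_uaug(df)
        sections["lengths_by_tata"] = self._lengths_by_tata(df)
        sections["exon_count"] = self._section_or_absent(
            lambda: _two_group(df, "exon_count", "uaug_class", ("uAUG_less", "uAUG"))
        )
        sections["ribosomal_density"] = self._density_section(df)
        sections["mrna_levels"] = self._mrna_section(df)
        sections["groseq"] = self._groseq_section(df)
        sections["tissue"] = self._tissue_section(df)
        sections["correlations"] = self._correlations(df)
        sections["expression_split"] = self._expression_split(df)
        return CoordinationResults(_jsonable(sections), self.config)

    # ---- sections ----------------------------------------------------- #
    @staticmethod
    def _section_or_absent(builder) -> Any:
        try:
            out = builder()
        except (KeyError, ValueError):
            return {"status": "input absent"}
        return out if out is not None else {"status": "input absent"}

    def _uaug_prevalence(self, df: pd.DataFrame) -> dict[str, Any]:
        if "tata_class" not in df or df["tata_class"].notna().sum() == 0:
            return {"status": "input absent"}
        out: dict[str, Any] = {}
        table3 = utr_features.uaug_prevalence_by_class(df, "tata_class")
        out["by_promoter_class"] = {
            str(idx): {
                "uAUG": int(row["uAUG"]),
                "uAUG_less": int(row["uAUG_less"]),
                "n": int(row["n"]),
                "pct_uaug": float(row["pct_uaug"]),
            }
            for idx, row in table3.iterrows()
        }
        res3 = group_stats.chi_square_prevalence(table3[["uAUG", "uAUG_less"]].to_numpy())
        out["chi_square_by_class"] = _test_dict(res3)

        sub = df[df["tata_class"].notna()].copy()
        sub["tata2"] = np.where(sub["tata_class"] == "tata_less", "tata_less", "tata")
        table2 = utr_features.uaug_prevalence_by_class(sub, "tata2")
        out["by_tata_vs_tataless"] = {
            str(idx): {
                "uAUG": int(row["uAUG"]),
                "uAUG_less": int(row["uAUG_less"]),
                "n": int(row["n"]),
                "pct_uaug": float(row["pct_uaug"]),
            }
            for idx, row in table2.iterrows()
        }
        out["chi_square_tata_vs_tataless"] = _test_dict(
            group_stats.chi_square_prevalence(table2[["uAUG", "uAUG_less"]].to_numpy())
        )
        # the complementary view: TATA frequency within each uAUG class
        out["pct_tata_by_uaug_class"] = {
            cls: float(
                100.0
                * (sub.loc[sub["uaug_class"] == cls, "tata2"] == "tata").mean()
            )
            for cls in ("uAUG", "uAUG_less")
        }
        return out

    def _lengths_by_uaug(self, df: pd.DataFrame) -> dict[str, Any]:
        return {
            feat: self._section_or_absent(
                lambda f=feat: _two_group(df, f, "uaug_class", ("uAUG_less", "uAUG"))
            )
            for feat in LENGTH_FEATURES
        }

    def _lengths_by_tata(self, df: pd.DataFrame) -> dict[str, Any]:
        if "tata_class" not in df or df["tata_class"].notna().sum() == 0:
            return {"status": "input absent"}
        out: dict[str, Any] = {}
        sub = df[df["tata_class"].notna()].copy()
        sub["tata2"] = np.where(sub["tata_class"] == "tata_less", "tata_less", "tata")
        for uaug_cls in ("uAUG_less", "uAUG"):
            grp = sub[sub["uaug_class"] == uaug_cls]
            out[uaug_cls] = {}
            for feat in LENGTH_FEATURES:
                entry = self._section_or_absent(
                    lambda g=grp, f=feat: _two_group(g, f, "tata2", ("tata", "tata_less"))
                )
                if isinstance(entry, dict) and "status" not in entry:
                    groups3 = [
                        grp.loc[grp["tata_class"] == c, feat].dropna().to_numpy(dtype=float)
                        for c in ("canonical", "one_mismatch", "tata_less")
                    ]
                    if all(g.size > 0 for g in groups3):
                        entry["kruskal_3class"] = _test_dict(group_stats.kruskal_wallis(groups3))
                out[uaug_cls][feat] = entry
        return out

    def _density_section(self, df: pd.DataFrame) -> dict[str, Any]:
        if "ribo_density" not in df:
            return {"status": "input absent"}
        sub = df[df["ribo_density"].notna()]
        if len(sub) == 0:
            return {"status": "input absent"}
        out: dict[str, Any] = {
            "by_uaug": self._section_or_absent(
                lambda: _two_group(sub, "ribo_density", "uaug_class", ("uAUG_less", "uAUG"))
            )
        }
        out["by_tata_within_uaug_class"] = self._tata_within(sub, "ribo_density")
        return out

    def _mrna_section(self, df: pd.DataFrame) -> dict[str, Any]:
        if "mrna_reads" not in df:
            return {"status": "input absent"}
        sub = df[df["mrna_reads"].notna()]
        if len(sub) == 0:
            return {"status": "input absent"}
        return {
            "by_uaug": self._section_or_absent(
                lambda: _two_group(sub, "mrna_reads", "uaug_class", ("uAUG_less", "uAUG"))
            )
        }

    def _groseq_section(self, df: pd.DataFrame) -> dict[str, Any]:
        if "groseq_rate" not in df:
            return {"status": "input absent"}
        sub = df[df["groseq_rate"].notna() & (df["groseq_background"] == False)]  # noqa: E712
        if len(sub) == 0:
            return {"status": "input absent"}
        out: dict[str, Any] = {
            "by_uaug": self._section_or_absent(
                lambda: _two_group(sub, "groseq_rate", "uaug_class", ("uAUG_less", "uAUG"))
            )
        }
        out["by_tata_within_uaug_class"] = self._tata_within(sub, "groseq_rate")
        out["n_background_excluded"] = int((df.get("groseq_background") == True).sum())  # noqa: E712
        return out

    def _tata_within(self, sub: pd.DataFrame, value: str) -> dict[str, Any]:
        if "tata_class" not in sub or sub["tata_class"].notna().sum() == 0:
            return {"status": "input absent"}
        s = sub[sub["tata_class"].notna()].copy()
        s["tata2"] = np.where(s["tata_class"] == "tata_less", "tata_less", "tata")
        return {
            uaug_cls: self._section_or_absent(
                lambda c=uaug_cls: _two_group(
                    s[s["uaug_class"] == c], value, "tata2", ("tata", "tata_less")
                )
            )
            for uaug_cls in ("uAUG_less", "uAUG")
        }

    def _tissue_section(self, df: pd.DataFrame) -> dict[str, Any]:
        if "tissue_mean" not in df:
            return {"status": "input absent"}
        has = df[df["tissue_mean"].notna()]
        if len(has) == 0:
            return {"status": "input absent"}
        above = has[has["tissue_mean"] >= self.config.tissue_threshold]
        out: dict[str, Any] = {}
        out["mean_by_uaug"] = self._section_or_absent(
            lambda: _two_group(above, "tissue_mean", "uaug_class", ("uAUG_less", "uAUG"))
        )
        out["max_by_uaug"] = self._section_or_absent(
            lambda: _two_group(above, "tissue_max", "uaug_class", ("uAUG_less", "uAUG"))
        )
        out["breadth_by_uaug"] = self._section_or_absent(
            lambda: _two_group(has, "tissue_breadth", "uaug_class", ("uAUG_less", "uAUG"))
        )
        out["n_below_background"] = int((has["tissue_mean"] < self.config.tissue_threshold).sum())
        return out

    def _correlations(self, df: pd.DataFrame) -> Any:
        pairs = [
            ("utr5_length", "te"),
            ("utr3_length", "te"),
            ("cds_length", "te"),
            ("ribo_density", "mrna_reads"),
            ("utr5_length", "mrna_reads"),
            ("cds_length", "mrna_reads"),
            ("utr3_length", "mrna_reads"),
        ]
        out = []
        for x, y in pairs:
            if x not in df or y not in df:
                continue
            sub = df[[x, y]].dropna()
            if len(sub) < 3:
                continue
            r = group_stats.spearman(sub[x], sub[y])
            out.append(
                {
                    "x": x,
                    "y": y,
                    "rho": r.rho,
                    "p_value": r.p_value,
                    "n": r.n,
                    "stars": star_annotation(r.p_value) if not math.isnan(r.p_value) else "NS",
                }
            )
        return out if out else {"status": "input absent"}

    def _expression_split(self, df: pd.DataFrame) -> dict[str, Any]:
        if "tissue_mean" not in df:
            return {"status": "input absent"}
        has = df[df["tissue_mean"].notna() & (df["tissue_mean"] >= self.config.tissue_threshold)]
        if len(has) < 4:
            return {"status": "input absent"}
        values = has.set_index("gene")["tissue_mean"]
        out: dict[str, Any] = {"prevalence": {}}
        for frac in self.config.top_fractions:
            top, bottom = em.split_by_expression(values, top_fraction=frac)
            t = has[has["gene"].isin(top)]
            b = has[has["gene"].isin(bottom)]
            counts = np.array(
                [
                    [(t["uaug_class"] == "uAUG").sum(), (t["uaug_class"] == "uAUG_less").sum()],
                    [(b["uaug_class"] == "uAUG").sum(), (b["uaug_class"] == "uAUG_less").sum()],
                ]
            )
            entry: dict[str, Any] = {
                "n_top": int(len(t)),
                "n_bottom": int(len(b)),
                "pct_uaug_top": float(100.0 * (t["uaug_class"] == "uAUG").mean()),
                "pct_uaug_bottom": float(100.0 * (b["uaug_class"] == "uAUG").mean()),
            }
            try:
                entry["chi_square"] = _test_dict(group_stats.chi_square_prevalence(counts))
            except ValueError:
                entry["chi_square"] = {"status": "degenerate table"}
            out["prevalence"][f"top_{frac:g}"] = entry
        # within each uAUG class: feature contrasts between top 25% and bottom
        frac = self.config.top_fractions[0]
        top, _ = em.split_by_expression(values, top_fraction=frac)
        marked = has.assign(split=np.where(has["gene"].isin(top), "top", "bottom"))
        out["features_within_uaug_class"] = {
            uaug_cls: {
                feat: self._section_or_absent(
                    lambda c=uaug_cls, f=feat: _two_group(
                        marked[marked["uaug_class"] == c], f, "split", ("top", "bottom")
                    )
                )
                for feat in LENGTH_FEATURES
            }
            for uaug_cls in ("uAUG_less", "uAUG")
        }
        return out


@dataclass
class CoordinationResults:
    """Fitted analysis report: nested sections, JSON/text serialization."""

    sections: dict[str, Any]
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __getitem__(self, key: str) -> Any:
        return self.sections[key]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.sections, sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def tests_frame(self) -> pd.DataFrame:
        """Flat table of every hypothesis test in the report."""
        rows: list[dict[str, Any]] = []

        def walk(node: Any, path: str) -> None:
            if isinstance(node, dict):
                if "p_value" in node and "statistic" in node:
                    rows.append(
                        {
                            "comparison": path,
                            "test": node.get("test", ""),
                            "statistic": node["statistic"],
                            "p_value": node["p_value"],
                            "direction": node.get("direction"),
                            "stars": node.get("stars", ""),
                            "n_per_group": ",".join(map(str, node.get("n_per_group", []))),
                        }
                    )
                for k, v in node.items():
                    if k != "groups":
                        walk(v, f"{path}/{k}" if path else str(k))
            elif isinstance(node, list):
                for i, v in enumerate(node):
                    walk(v, f"{path}[{i}]")

        walk(self.sections, "")
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable digest of the main comparisons."""
        lines = ["Regulatory coordination analysis", "=" * 48]
        uni = self.sections.get("universe", {})
        lines.append(f"genes analysed: {uni.get('n_genes', '?')}")
        prev = self.sections.get("uaug_prevalence", {})
        if "by_tata_vs_tataless" in prev:
            lines.append("")
            lines.append("uAUG prevalence by promoter class (% uAUG):")
            for cls, row in prev["by_promoter_class"].items():
                lines.append(f"  {cls:<14} {row['pct_uaug']:6.1f}%  (n={row['n']})")
            chi = prev["chi_square_by_class"]
            lines.append(
                f"  chi-square: {chi['statistic']:.2f}, p = {chi['p_value']:.3g} {chi['stars']}"
            )
        frame = self.tests_frame()
        if len(frame):
            lines.append("")
            lines.append(f"hypothesis tests run: {len(frame)}")
            sig = (frame["p_value"] < 0.05).sum()
            lines.append(f"significant at 0.05: {sig}")
        for name in ("ribosomal_density", "mrna_levels", "groseq"):
            sec = self.sections.get(name, {})
            entry = sec.get("by_uaug") if isinstance(sec, dict) else None
            if isinstance(entry, dict) and "p_value" in entry:
                d = {1: "uAUG_less > uAUG", -1: "uAUG_less < uAUG", 0: "no shift"}[
                    entry["direction"]
                ]
                lines.append(
                    f"{name} by uAUG: {d}, p = {entry['p_value']:.3g} {entry['stars']}"
                )
        return "\n".join(lines)


def run_analysis(
    annotation: str | Path,
    promoters: str | Path | None = None,
    genome: str | Path | None = None,
    utr5: str | Path | None = None,
    utr3: str | Path | None = None,
    cds: str | Path | None = None,
    ribo: str | Path | None = None,
    groseq: str | Path | None = None,
    tissues: str | Path | None = None,
    config: AnalysisConfig | None = None,
) -> CoordinationResults:
    """Run the full pipeline from files and return the fitted report.

    Promoter windows come either from a per-gene promoter FASTA or are
    extracted from a genome FASTA.  Optional layers (ribosome profiling,
    Gro-seq, tissue atlas) that are not supplied leave their report
    sections marked absent; missing required files raise with the path
    named.
    """
    config = config or AnalysisConfig()
    annotation = Path(annotation)
    if not annotation.exists():
        raise FileNotFoundError(f"annotation file not found: {annotation}")
    genes = genome_io.dedupe_by_symbol(genome_io.read_genepred(annotation).genes)

    calls = None
    if promoters is not None:
        windows = genome_io.read_fasta(promoters)
        calls, _ = classify_cohort(windows, MotifSpec(config.motif, config.max_mismatch))
    elif genome is not None:
        gen = genome_io.load_genome_fasta(genome)
        windows = {}
        for g in genes:
            w = genome_io.extract_promoter_window(g, gen)
            if w is not None:
                windows[g.symbol] = w
        calls, _ = classify_cohort(windows, MotifSpec(config.motif, config.max_mismatch))

    regions = utr_features.build_regions(
        utr5=genome_io.read_fasta(utr5) if utr5 else None,
        utr3=genome_io.read_fasta(utr3) if utr3 else None,
        cds=genome_io.read_fasta(cds) if cds else None,
    )
    features, _ = utr_features.build_feature_table(genes, regions, calls)
    if len(features) == 0:
        raise ValueError("gene-id join resolved no genes between annotation and sequences")
    model = RegulatoryCoordination.from_tables(
        features,
        ribo=em.read_count_table(ribo, ("gene", "footprint_reads", "mrna_reads")) if ribo else None,
        groseq=em.read_count_table(groseq, ("gene", "reads_beyond_1kb")) if groseq else None,
        tissues=em.read_tissue_matrix(tissues) if tissues else None,
        config=config,
    )
    return model.fit()
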