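"""Report assembly: summary statistics recomputed from data.

All numeric report values are recomputed from the underlying records; annotation
columns carried by the packaged tables (printed read counts, E-values) are
echoed as clearly labelled "as-printed" fields only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import pandas as pd

from . import identify, phylo
from .io_formats import FixtureTables, load_fixtures
from .preprocess import LengthHistogram

SCHEMA_VERSION = 1


def summarize_variants(table1: pd.DataFrame) -> dict:
    """Variant/family/5'-nucleotide statistics from a mature-variant table
    (columns family, sequence)."""
    pairs = list(zip(table1["family"], table1["sequence"]))
    tn = identify.terminal_nt_summary(pairs)
    families = list(dict.fromkeys(table1["family"]))
    merged = list(dict.fromkeys(identify.merge_family_label(f) for f in families))
    frac_u = tn.n_u_variants / tn.n_variants if tn.n_variants else 0.0
    return {
        "n_variants": tn.n_variants,
        "n_families_split": len(families),
        "n_families_merged": len(merged),
        "five_prime_base_counts": tn.base_counts,
        "n_five_prime_u_variants": tn.n_u_variants,
        "n_families_with_five_prime_u": len(tn.families_with_u),
        "families_majority_a": sorted(tn.families_majority_a),
        "five_prime_u_fraction": frac_u,
        "five_prime_u_percent": round(100 * frac_u),
    }


def summarize_origins(fixtures: Optional[FixtureTables] = None) -> dict:
    """Dollo origin census and fern-shared column censuses from the packaged
    presence matrix and cladogram."""
    fx = fixtures or load_fixtures()
    tree = phylo.load_tree(fx.fig1_tree)
    assignments = phylo.assign_origins(fx.fig3_matrix, tree)
    census = phylo.node_census(assignments)
    return {
        "node_census_counts": {node: len(fams) for node, fams in census.items()},
        "node_census_families": census,
        "shared_with_ferns": {
            taxon: phylo.taxon_census(fx.fig3_matrix, taxon, intersect_with="ferns")
            for taxon in ("liverworts", "mosses", "lycophytes")
        },
    }


def summarize_targets(table2: pd.DataFrame) -> dict:
    return {
        "n_target_rows": len(table2),
        "n_families_with_conserved_targets": int(table2["family"].nunique()),
        "max_expectation_printed": float(pd.to_numeric(table2["expectation"]).max()),
    }


@dataclass
class Report:
    variants: dict = field(default_factory=dict)
    origins: dict = field(default_factory=dict)
    targets: dict = field(default_factory=dict)
    histogram: Optional[dict] = None
    schema_version: int = SCHEMA_VERSION

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def fixture_report() -> Report:
    """Identification + target + origin summary computed from the packaged tables."""
    fx = load_fixtures()
    return Report(
        variants=summarize_variants(fx.table1),
        origins=summarize_origins(fx),
        targets=summarize_targets(fx.table2),
    )


def histogram_dict(hist: LengthHistogram) -> dict:
    return {
        "counts": hist.display_counts(),
        "percentages": {L: hist.percentages.get(L, 0.0) for L in hist.display_counts()},
        "mode": hist.mode,
    }


def render_summary(report: Report) -> str:
    """Human-readable run summary."""
    lines = []
    v = report.variants
    if v:
        lines.append(
            f"{v['n_variants']} conserved miRNA variants in {v['n_families_split']} families "
            f"({v['n_families_merged']} with superfamilies merged)"
        )
        lines.append(
            f"{v['n_five_prime_u_variants']}/{v['n_variants']} variants 5'-U "
            f"({v['five_prime_u_percent']}%), spanning "
            f"{v['n_families_with_five_prime_u']} families"
        )
    if report.histogram:
        lines.append(f"length-distribution mode: {report.histogram['mode']} nt")
    t = report.targets
    if t:
        n = t["n_families_with_conserved_targets"]
        lines.append(
            f"{n} families with conserved predicted targets" if n else "0 sites"
        )
    o = report.origins
    if o:
        counts = ", ".join(f"{node}: {n}" for node, n in sorted(o["node_census_counts"].items()))
        lines.append(f"origin census — {counts}")
        shared = o["shared_with_ferns"]
        lines.append(
            "families shared with ferns — "
            + ", ".join(f"{k}: {v}" for k, v in shared.items())
        )
    return "\n".join(lines)
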