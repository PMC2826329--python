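"""Genome-wide recombination rates (cM/Mb) from genetic maps.

The rate for a species is its corrected total genetic map length (cM)
divided by its physical genome size (Mb).  Map lengths are corrected for
marker density and undetected terminal crossovers; genome sizes may be
given directly in Mb or as a haploid C-value in pg (1 pg = 978 Mb).
Records are filtered on map coverage (>= 60% of the genome) and on the
number of SSR loci behind the heterozygosity estimate (>= 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpeciesRecord",
    "correct_map_length",
    "genome_size_mb",
    "build_rate_table",
    "domestication_check",
    "read_species_table",
    "write_species_table",
    "PG_TO_MB",
    "MIN_MAP_COVERAGE",
    "MIN_SSR_LOCI",
]

PG_TO_MB = 978.0  # 1 pg haploid DNA ~ 978 Mb
MIN_MAP_COVERAGE = 0.60
MIN_SSR_LOCI = 5

LIFE_FORMS = ("herb", "shrub", "tree")
TAXON_GROUPS = ("angiosperm", "conifer")


@dataclass
class SpeciesRecord:
    """One species' map, genome-size and diversity data.

    Per-chromosome map lengths (cM) and marker counts drive the map-length
    correction; exactly one of ``genome_size_mb`` / ``c_value_pg`` must be
    given.  ``he`` is expected heterozygosity at SSR loci, estimated from
    ``n_ssr_loci`` microsatellites.
    """

    species: str
    life_form: str
    taxon_group: str
    chrom_lengths_cm: Sequence[float]
    chrom_markers: Sequence[int]
    n_chromosomes: Optional[int] = None
    genome_size_mb: Optional[float] = None
    c_value_pg: Optional[float] = None
    map_coverage: float = 1.0
    he: float = 0.5
    n_ssr_loci: int = 5
    domesticated: bool = False
    family: str = ""

    def __post_init__(self) -> None:
        if self.life_form not in LIFE_FORMS:
            raise ValueError(f"unknown life_form {self.life_form!r}")
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(f"unknown taxon_group {self.taxon_group!r}")
        if (self.genome_size_mb is None) == (self.c_value_pg is None):
            raise ValueError(
                "exactly one of genome_size_mb / c_value_pg must be given"
            )
        if len(self.chrom_lengths_cm) != len(self.chrom_markers):
            raise ValueError("chromosome lengths and marker counts misaligned")
        if any(l <= 0 for l in self.chrom_lengths_cm):
            raise ValueError("map lengths must be positive")
        if not 0.0 <= self.he <= 1.0:
            raise ValueError("He must lie in [0, 1]")
        if self.n_chromosomes is None:
            self.n_chromosomes = len(self.chrom_lengths_cm)


def correct_map_length(
    chrom_lengths: Sequence[float],
    chrom_markers: Sequence[int],
    method: str = "add2s",
    n_chromosomes: Optional[int] = None,
) -> float:
    """Correct a genetic map length for undetected terminal crossovers.

    ``add2s`` (default): the average inter-marker spacing
    ``s = sum(L_c) / sum(m_c - 1)`` is added twice per chromosome, once
    beyond each terminal marker: ``corrected = sum(L_c) + 2 * s * C``.
    ``chakravarti``: each chromosome's length is inflated by
    ``(m_c + 1) / (m_c - 1)``.

    Totals-only data can be passed as single-element lists with
    ``n_chromosomes`` set; the spacing denominator then uses
    ``m_total - C`` (one fewer interval than markers per chromosome).
    """
    lengths = [float(x) for x in chrom_lengths]
    markers = [int(x) for x in chrom_markers]
    if len(lengths) != len(markers) or not lengths:
        raise ValueError("lengths and marker counts must align and be non-empty")
    if any(l < 0 for l in lengths):
        raise ValueError("negative map length")
    C = n_chromosomes if n_chromosomes is not None else len(lengths)
    if n_chromosomes is not None and len(lengths) == 1:
        intervals = markers[0] - C
    else:
        intervals = sum(m - 1 for m in markers)
        if any(m < 2 for m in markers):
            raise ValueError("every chromosome needs at least 2 markers")
    if intervals <= 0:
        raise ValueError("fewer marker intervals than chromosomes")
    total = sum(lengths)
    if method == "add2s":
        s = total / intervals
        return total + 2.0 * s * C
    if method == "chakravarti":
        if len(lengths) == 1 and n_chromosomes is not None and C > 1:
            raise ValueError("chakravarti needs per-chromosome data")
        return sum(l * (m + 1) / (m - 1) for l, m in zip(lengths, markers))
    raise ValueError(f"unknown correction method {method!r}")


def genome_size_mb(record: SpeciesRecord) -> float:
    """Physical genome size in Mb (C-value converted at 1 pg = 978 Mb)."""
    if record.c_value_pg is not None:
        return record.c_value_pg * PG_TO_MB
    return float(record.genome_size_mb)


def build_rate_table(
    records: Sequence[SpeciesRecord],
    method: str = "add2s",
):
    """Assemble the per-species rate table, applying the inclusion filters.

    Records with map coverage below 60% or fewer than five SSR loci are
    excluded; the exclusion log names the violated rule.  Returns
    ``(table, exclusions)`` where ``table`` has one row per retained
    species with the corrected map length, genome size, rate (cM/Mb) and
    natural-log rate.  The correction method is recorded in
    ``table.attrs["correction_method"]``.
    """
    rows, dropped = [], []
    for rec in records:
        reasons = []
        if rec.map_coverage < MIN_MAP_COVERAGE:
            reasons.append(f"coverage<{MIN_MAP_COVERAGE:.2f}")
        if rec.n_ssr_loci < MIN_SSR_LOCI:
            reasons.append(f"ssr_loci<{MIN_SSR_LOCI}")
        if reasons:
            dropped.append({"species": rec.species, "reason": ";".join(reasons)})
            continue
        corrected = correct_map_length(
            rec.chrom_lengths_cm, rec.chrom_markers, method=method,
            n_chromosomes=rec.n_chromosomes,
        )
        size = genome_size_mb(rec)
        rate = corrected / size
        rows.append({
            "species": rec.species,
            "corrected_cm": corrected,
            "genome_mb": size,
            "rate": rate,
            "log_rate": math.log(rate),
            "he": rec.he,
            "life_form": rec.life_form,
            "taxon_group": rec.taxon_group,
        })
    if not rows:
        raise ValueError("no species passed the inclusion filters")
    table = pd.DataFrame(rows).sort_values("species").reset_index(drop=True)
    table.attrs["correction_method"] = method
    exclusions = pd.DataFrame(dropped, columns=["species", "reason"])
    return table, exclusions


def domestication_check(table: pd.DataFrame, pairs: Sequence):
    """Paired test of log rates between domesticated species and wild kin.

    Wilcoxon signed-rank on within-pair log-rate differences.  Returns a
    dict with the statistic, the number of pairs, the p-value and a
    pooling recommendation (pool when p > 0.05).  With every difference
    zero the test is degenerate and p is reported as 1.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 domesticated/wild pairs")
    idx = table.set_index("species")["log_rate"]
    diffs = []
    for dom, wild in pairs:
        if dom not in idx.index or wild not in idx.index:
            raise KeyError(f"pair member missing from table: {dom!r}/{wild!r}")
        diffs.append(idx[dom] - idx[wild])
    diffs = np.asarray(diffs)
    if np.allclose(diffs, 0.0):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(diffs)
    return {
        "statistic": float(stat),
        "n_pairs": len(diffs),
        "p_value": float(p),
        "pool": bool(p > 0.05),
    }


# -- delimited text I/O -----------------------------------------------------

_LIST_SEP = ";"


def read_species_table(path, sep: str = "\t"):
    """Read species records from delimited text.

    Per-chromosome fields (``chrom_lengths_cm``, ``chrom_markers``) are
    semicolon-joined lists; empty genome-size cells mean "not given".
    """
    df = pd.read_csv(path, sep=sep)
    records = []
    for _, row in df.iterrows():
        records.append(SpeciesRecord(
            species=row["species"],
            life_form=row["life_form"],
            taxon_group=row["taxon_group"],
            chrom_lengths_cm=[float(x) for x in str(row["chrom_lengths_cm"]).split(_LIST_SEP)],
            chrom_markers=[int(x) for x in str(row["chrom_markers"]).split(_LIST_SEP)],
            n_chromosomes=int(row["n_chromosomes"]) if not pd.isna(row.get("n_chromosomes", np.nan)) else None,
            genome_size_mb=float(row["genome_size_mb"]) if not pd.isna(row.get("genome_size_mb", np.nan)) else None,
            c_value_pg=float(row["c_value_pg"]) if not pd.isna(row.get("c_value_pg", np.nan)) else None,
            map_coverage=float(row.get("map_coverage", 1.0)),
            he=float(row["he"]),
            n_ssr_loci=int(row.get("n_ssr_loci", MIN_SSR_LOCI)),
            domesticated=bool(row.get("domesticated", False)),
            family=str(row.get("family", "")),
        ))
    return records


def write_species_table(records: Sequence[SpeciesRecord], path, sep: str = "\t") -> None:
    rows = []
    for r in records:
        rows.append({
            "species": r.species,
            "family": r.family,
            "life_form": r.life_form,
            "taxon_group": r.taxon_group,
            "chrom_lengths_cm": _LIST_SEP.join(f"{x:.6g}" for x in r.chrom_lengths_cm),
            "chrom_markers": _LIST_SEP.join(str(int(x)) for x in r.chrom_markers),
            "n_chromosomes": r.n_chromosomes,
            "genome_size_mb": r.genome_size_mb,
            "c_value_pg": r.c_value_pg,
            "map_coverage": r.map_coverage,
            "he": r.he,
            "n_ssr_loci": r.n_ssr_loci,
            "domesticated": r.domesticated,
        })
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
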