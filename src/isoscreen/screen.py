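"""Score, filter and rank isoform families by divergence of ribosome density.

The ranking statistic is the sample coefficient of variation of member
densities ("normalized SD": standard deviation with the n-1 denominator,
divided by the mean).  Under this definition a two-member family tops out at
sqrt(2) ~= 1.414 (one member silent), which makes the 1.4 selection threshold
an "extreme two-member divergence" line.  A log-scale variant is exposed as a
config option but the raw-density definition is the default and must not be
changed silently.

Filters: families whose best-translated member has density < 1 are discarded;
survivors are ranked by normalized SD descending and the top N at or above
the SD threshold are selected.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import density as density_mod
from . import families as families_mod
from .families import IsoformFamily
from .genome_io import CoverageTrack, GeneLocus, SequenceRecord, TranscriptModel

log = logging.getLogger(__name__)

DEFAULT_MIN_MAX_DENSITY = 1.0
DEFAULT_SD_THRESHOLD = 1.4
DEFAULT_TOP_N = 100


class AllSilentFamilyError(ValueError):
    """Every member density is zero: the normalized SD is undefined."""


def normalized_sd(values: Sequence[float], log_scale: bool = False) -> float:
    """Sample coefficient of variation: SD (n-1 denominator) / mean.

    With ``log_scale=True`` the statistic is computed on log10 densities
    (requires all values > 0).  Fewer than two values is an error; an
    all-zero family raises :class:`AllSilentFamilyError`.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("normalized SD needs at least two values")
    if np.any(arr < 0):
        raise ValueError("densities must be non-negative")
    if log_scale:
        if np.any(arr <= 0):
            raise ValueError("log-scale normalized SD requires positive values")
        arr = np.log10(arr)
    mean = arr.mean()
    if mean == 0:
        if not log_scale:
            raise AllSilentFamilyError("all member densities are zero")
        raise ValueError("log-scale mean is zero; statistic undefined")
    return float(arr.std(ddof=1) / mean)


@dataclass
class FamilyScore:
    """A scored family: member densities, normalized SD and filter flags."""

    family_id: str
    member_densities: dict[str, float]
    normalized_sd: float
    max_density: float
    incomplete: bool = False
    passed_min_density: bool | None = None
    rank: int | None = None
    selected: bool = False

    def __post_init__(self) -> None:
        if self.member_densities:
            expect = max(self.member_densities.values())
            if not math.isclose(self.max_density, expect, rel_tol=1e-12):
                raise ValueError("max_density inconsistent with member densities")


def score_families(
    families: Sequence[IsoformFamily],
    densities: Mapping[str, float],
    log_scale: bool = False,
) -> list[FamilyScore]:
    """Attach densities and the normalized-SD statistic to each family.

    Families with members lacking a density are scored on the available
    members and flagged ``incomplete`` (excluded from selection by default).
    All-silent families get normalized_sd = NaN and are never selectable.
    """
    scores: list[FamilyScore] = []
    for fam in families:
        present = {g: densities[g] for g in fam.member_gene_ids if g in densities}
        missing = [g for g in fam.member_gene_ids if g not in densities]
        if missing:
            log.warning(
                "family %s: no density for members %s; flagged incomplete",
                fam.family_id,
                ",".join(missing),
            )
        if len(present) < 2:
            scores.append(
                FamilyScore(
                    family_id=fam.family_id,
                    member_densities=present,
                    normalized_sd=float("nan"),
                    max_density=max(present.values()) if present else 0.0,
                    incomplete=True,
                )
            )
            continue
        try:
            nsd = normalized_sd(list(present.values()), log_scale=log_scale)
        except AllSilentFamilyError:
            nsd = float("nan")
        scores.append(
            FamilyScore(
                family_id=fam.family_id,
                member_densities=present,
                normalized_sd=nsd,
                max_density=max(present.values()),
                incomplete=bool(missing),
            )
        )
    return scores


def apply_filters(
    scores: Sequence[FamilyScore],
    min_max_density: float = DEFAULT_MIN_MAX_DENSITY,
) -> list[FamilyScore]:
    """Set passed_min_density: max member density >= threshold (inclusive)."""
    for s in scores:
        s.passed_min_density = s.max_density >= min_max_density
    return list(scores)


def rank_and_select(
    scores: Sequence[FamilyScore],
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    top_n: int = DEFAULT_TOP_N,
    include_incomplete: bool = False,
) -> list[FamilyScore]:
    """Rank surviving families by normalized SD (desc, ties by family_id).

    ``selected`` = passed filters AND normalized_sd >= sd_threshold AND
    rank <= top_n.  Filtered-out families keep rank None.  Returns all scores,
    ranked ones first.
    """
    eligible = [
        s
        for s in scores
        if s.passed_min_density
        and (include_incomplete or not s.incomplete)
        and not math.isnan(s.normalized_sd)
    ]
    eligible.sort(key=lambda s: (-s.normalized_sd, s.family_id))
    for i, s in enumerate(eligible, start=1):
        s.rank = i
        s.selected = s.normalized_sd >= sd_threshold and i <= top_n
    eligible_ids = {id(s) for s in eligible}
    rest = [s for s in scores if id(s) not in eligible_ids]
    for s in rest:
        s.rank = None
        s.selected = False
    return eligible + rest


@dataclass
class ScreenConfig:
    """All thresholds of the end-to-end screen, defaulting to the published values."""

    identity_threshold: float = families_mod.DEFAULT_IDENTITY_THRESHOLD
    length_ratio_threshold: float = families_mod.DEFAULT_LENGTH_RATIO_THRESHOLD
    strict_thresholds: bool = False
    min_max_density: float = DEFAULT_MIN_MAX_DENSITY
    sd_threshold: float = DEFAULT_SD_THRESHOLD
    top_n: int = DEFAULT_TOP_N
    window_codons: int = density_mod.DEFAULT_WINDOW_CODONS
    aggregation_mode: str = "sum_tracks"
    log_scale: bool = False
    exclude_out_of_frame: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScreenReport:
    """run_screen output: scored families plus run metadata."""

    scores: list[FamilyScore]
    families: list[IsoformFamily]
    densities: dict[str, float]
    config: ScreenConfig
    warnings: list[str] = field(default_factory=list)

    def selected(self) -> list[FamilyScore]:
        return [s for s in self.scores if s.selected]


def _transcript_for_gene(
    locus: GeneLocus, protein: SequenceRecord | None
) -> TranscriptModel:
    """The transcript encoding the chosen protein, else the longest CDS."""
    if protein is not None:
        for tx in locus.transcripts:
            if tx.protein_id and tx.protein_id == protein.id:
                return tx
    return min(locus.transcripts, key=lambda t: (-t.cds_length, t.transcript_id))


def run_screen(
    proteins: Mapping[str, SequenceRecord],
    loci: Sequence[GeneLocus],
    tracks: Sequence[CoverageTrack],
    config: ScreenConfig | None = None,
) -> ScreenReport:
    """End-to-end screen: cluster proteins, quantify densities, score families.

    *proteins* maps gene_id to the representative (longest) protein; use
    :func:`isoscreen.families.longest_protein_per_locus` to build it from
    annotated loci.  Genes present in the proteome but absent from the
    annotation are logged and their families flagged incomplete.
    """
    config = config or ScreenConfig()
    warnings: list[str] = []

    fams = families_mod.build_families(
        proteins,
        identity_threshold=config.identity_threshold,
        length_ratio_threshold=config.length_ratio_threshold,
        strict=config.strict_thresholds,
    )

    loci_by_gene = {locus.gene_id: locus for locus in loci}
    densities: dict[str, float] = {}
    family_genes = {g for fam in fams for g in fam.member_gene_ids}
    for gene_id in sorted(family_genes):
        locus = loci_by_gene.get(gene_id)
        if locus is None:
            msg = f"gene {gene_id} missing from annotation; no density"
            warnings.append(msg)
            log.warning(msg)
            continue
        tx = _transcript_for_gene(locus, proteins.get(gene_id))
        if config.exclude_out_of_frame and not tx.in_frame:
            msg = f"gene {gene_id}: CDS length not divisible by 3; excluded"
            warnings.append(msg)
            log.warning(msg)
            continue
        rd = density_mod.composite_density(
            tracks, tx, mode=config.aggregation_mode, n_codons=config.window_codons
        )
        densities[gene_id] = rd.characteristic_density

    scores = score_families(fams, densities, log_scale=config.log_scale)
    apply_filters(scores, min_max_density=config.min_max_density)
    rank_and_select(scores, sd_threshold=config.sd_threshold, top_n=config.top_n)
    return ScreenReport(
        scores=scores,
        families=fams,
        densities=densities,
        config=config,
        warnings=warnings,
    )


def write_report_tsv(report: ScreenReport, path: str | Path) -> None:
    """Deterministic TSV: metadata as '#' header lines, one row per family."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in sorted(report.config.to_dict().items()):
            fh.write(f"# {key}: {value}\n")
        fh.write(
            "family_id\trank\tselected\tpassed_min_density\tincomplete\t"
            "normalized_sd\tmax_density\tmembers\tdensities\n"
        )
        ranked = sorted(
            report.scores,
            key=lambda s: (s.rank is None, s.rank if s.rank is not None else 0, s.family_id),
        )
        for s in ranked:
            members = ",".join(sorted(s.member_densities))
            dens = ",".join(
                f"{s.member_densities[g]:.6g}" for g in sorted(s.member_densities)
            )
            nsd = "nan" if math.isnan(s.normalized_sd) else f"{s.normalized_sd:.6f}"
            fh.write(
                f"{s.family_id}\t{s.rank if s.rank is not None else ''}\t"
                f"{int(s.selected)}\t{int(bool(s.passed_min_density))}\t"
                f"{int(s.incomplete)}\t{nsd}\t{s.max_density:.6g}\t"
                f"{members}\t{dens}\n"
            )


def write_report_json(report: ScreenReport, path: str | Path) -> None:
    payload = {
        "config": report.config.to_dict(),
        "warnings": report.warnings,
        "families": [
            {
                "family_id": s.family_id,
                "rank": s.rank,
                "selected": s.selected,
                "passed_min_density": s.passed_min_density,
                "incomplete": s.incomplete,
                "normalized_sd": None
                if math.isnan(s.normalized_sd)
                else s.normalized_sd,
                "max_density": s.max_density,
                "member_densities": dict(sorted(s.member_densities.items())),
            }
            for s in report.scores
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
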