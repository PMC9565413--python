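"""Gene-annotation statistics: transposon and support filters, Pfam
domain-count z-scores, and hypergeometric term enrichment with FDR control.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneDomainAnnotation",
    "GeneEvidence",
    "DomainCountMatrix",
    "EnrichmentResult",
    "DEFAULT_TRANSPOSON_TERMS",
    "flag_transposon_genes",
    "filter_unsupported_genes",
    "pfam_zscores",
    "hypergeometric_enrichment",
    "bh_adjust",
    "read_gene_domain_table",
    "read_evidence_table",
    "read_term_map",
]

#: Pfam description substrings marking transposon-related domains.
DEFAULT_TRANSPOSON_TERMS: tuple[str, ...] = (
    "transcriptase",
    "transposase",
    "gag",
    "env",
    "transposon",
    "repetitive element",
    "RNA-directed DNA polymerase",
    "pol protein",
    "non-LTR retrotransposon",
    "mobile element",
    "retroelement",
    "retrovirus",
    "Retroviral",
    "group-specific antigen",
)

#: Terms shorter than this many characters must match as whole tokens, so
#: "env" does not fire inside e.g. "envelope-unrelated" compound words.
_TOKEN_MATCH_BELOW = 5


@dataclass(frozen=True)
class GeneDomainAnnotation:
    """Pfam domains annotated on one gene."""

    gene_id: str
    domains: tuple[tuple[str, str], ...]  # (domain_id, description)


@dataclass(frozen=True)
class GeneEvidence:
    """Support status of one predicted gene."""

    gene_id: str
    has_external_support: bool
    has_functional_annotation: bool


@dataclass
class DomainCountMatrix:
    """Per-species Pfam domain counts (species x domains) with a focal species."""

    counts: pd.DataFrame  # index = species, columns = domain ids
    focal_species: str

    def __post_init__(self) -> None:
        if self.focal_species not in self.counts.index:
            raise ValueError(f"focal species {self.focal_species!r} not in matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("domain counts must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path, focal_species: str) -> "DomainCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df, focal_species=focal_species)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    study_hits: int
    study_size: int
    background_hits: int
    background_size: int
    p_raw: float
    p_adjusted: float
    significant: bool


def _term_matchers(terms: Sequence[str]):
    matchers = []
    for term in terms:
        t = term.lower()
        if len(t) < _TOKEN_MATCH_BELOW:
            matchers.append(re.compile(rf"\b{re.escape(t)}\b").search)
        else:
            matchers.append(lambda desc, t=t: t in desc)
    return matchers


def flag_transposon_genes(
    annotations: Iterable[GeneDomainAnnotation],
    term_list: Sequence[str] = DEFAULT_TRANSPOSON_TERMS,
) -> set[str]:
    """Genes where strictly more than half the Pfam domains look transposon-derived.

    A domain matches when any term occurs in its description,
    case-insensitively; terms shorter than 5 characters must match as whole
    tokens.  Genes without domains are never flagged.
    """
    if not term_list:
        raise ValueError("term list must be non-empty")
    matchers = _term_matchers(term_list)
    flagged: set[str] = set()
    for ann in annotations:
        if not ann.domains:
            continue
        n_match = sum(
            1
            for _, desc in ann.domains
            if any(m(desc.lower()) for m in matchers)
        )
        if n_match * 2 > len(ann.domains):
            flagged.add(ann.gene_id)
    return flagged


def filter_unsupported_genes(evidence_records: Iterable[GeneEvidence]) -> set[str]:
    """Genes to remove: no external support AND no functional annotation."""
    removed: set[str] = set()
    seen: set[str] = set()
    for rec in evidence_records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
        if not rec.has_external_support and not rec.has_functional_annotation:
            removed.add(rec.gene_id)
    return removed


def pfam_zscores(
    matrix: DomainCountMatrix,
    z_threshold: float = 1.96,
    include_focal: bool = False,
) -> pd.DataFrame:
    """Per-domain z-score of the focal species' count against the other species.

    z = (count_focal - mean_baseline) / sd_baseline with the sample standard
    deviation (n-1 denominator).  By default the baseline excludes the focal
    species; ``include_focal`` switches to the all-species baseline.  Calls:
    "expanded" for z > ``z_threshold``, "contracted" for z < -``z_threshold``,
    otherwise "neutral".  With zero baseline spread, z is 0 when the focal
    count equals the mean and signed infinity otherwise (the call follows
    the sign).

    Returns a DataFrame indexed by domain id with columns ``count_focal``,
    ``mean``, ``sd``, ``z``, ``call``.
    """
    baseline = matrix.counts if include_focal else matrix.counts.drop(index=matrix.focal_species)
    if len(baseline) < 3:
        raise ValueError("need at least 3 baseline species for z-scores")
    focal = matrix.counts.loc[matrix.focal_species].astype(float)
    mean = baseline.mean(axis=0)
    sd = baseline.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (focal - mean) / sd
    z = z.where(sd > 0, np.sign(focal - mean) * np.inf)
    z = z.where(~((sd == 0) & (focal == mean)), 0.0)
    call = pd.Series("neutral", index=z.index)
    call[z > z_threshold] = "expanded"
    call[z < -z_threshold] = "contracted"
    return pd.DataFrame(
        {"count_focal": focal, "mean": mean, "sd": sd, "z": z, "call": call}
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    study_genes: Iterable[str],
    background_genes: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> list[EnrichmentResult]:
    """One-sided over-representation test per term, BH-corrected.

    For each term with at least one background gene, the raw p-value is
    P(X >= k) under hypergeometric(N, K, n) with N the background size, K
    the background genes carrying the term, n the study size and k the
    study genes carrying the term.  Significance is ``p_adjusted < alpha``
    (or raw p with ``use_adjusted=False``).  Results are sorted by raw p.
    """
    study = set(study_genes)
    background = set(background_genes)
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    N, n = len(background), len(study)
    term_bg: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in background:
        for term in term_map.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1
    terms = sorted(term_bg)
    p_raw = np.array(
        [stats.hypergeom.sf(term_study.get(t, 0) - 1, N, term_bg[t], n) for t in terms]
    )
    p_adj = bh_adjust(p_raw) if terms else np.array([])
    results = [
        EnrichmentResult(
            term_id=t,
            study_hits=term_study.get(t, 0),
            study_size=n,
            background_hits=term_bg[t],
            background_size=N,
            p_raw=float(pr),
            p_adjusted=float(pa),
            significant=bool((pa if use_adjusted else pr) < alpha),
        )
        for t, pr, pa in zip(terms, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


# --- TSV readers -----------------------------------------------------------


def read_gene_domain_table(path: str | Path) -> list[GeneDomainAnnotation]:
    """Read a gene -> Pfam domain table.

    Format: ``gene_id <tab> domain_id <tab> description`` with one row per
    domain occurrence; a gene listed with an empty domain_id has no domains.
    """
    df = pd.read_csv(
        path, sep="\t", names=["gene_id", "domain_id", "description"],
        dtype=str, keep_default_na=False,
    )
    out: list[GeneDomainAnnotation] = []
    for gene_id, sub in df.groupby("gene_id", sort=False):
        domains = tuple(
            (r.domain_id, r.description)
            for r in sub.itertuples()
            if r.domain_id
        )
        out.append(GeneDomainAnnotation(gene_id=gene_id, domains=domains))
    return out


def read_evidence_table(path: str | Path) -> list[GeneEvidence]:
    """Read ``gene_id <tab> has_external_support <tab> has_functional_annotation``
    with boolean columns given as 0/1 or true/false."""

    def _to_bool(x: str) -> bool:
        return str(x).strip().lower() in ("1", "true", "yes")

    df = pd.read_csv(
        path, sep="\t", names=["gene_id", "support", "annotation"], dtype=str
    )
    return [
        GeneEvidence(r.gene_id, _to_bool(r.support), _to_bool(r.annotation))
        for r in df.itertuples()
    ]


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read ``gene_id <tab> comma-separated term ids`` into a mapping."""
    out: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, _, terms = line.partition("\t")
            out[gene] = {t for t in terms.split(",") if t}
    return out
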