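"""Randomization-based gene-set comparison against the network null.

The observed behaviour of a gene class (e.g. the fraction of oncogenes
significantly close to a pathway, or the fraction of activating paths it
sends into a pathway) is compared against the same statistic evaluated on
random gene lists drawn without replacement from the network universe
(by default 1000 lists of 700 genes, mirroring the size of the curated
cancer-gene catalogue).

The test treats the observed value as a single draw and asks whether it is
compatible with the null distribution of replicate fractions: a two-sided
one-sample t comparison ``t = (obs - mean_null) / (sd_null * sqrt(1 + 1/n))``
with ``n - 1`` degrees of freedom.  Scaling by the null spread (rather than
the standard error of the null mean) keeps the test calibrated: a random
list is starred at the * level in ~2.5% of studies.  The naive
standard-error variant is available as ``method="mean"``.

Stars follow the convention * p<0.025, ** p<0.0025, *** p<0.00025,
**** p<0.000025 (strict inequalities, two-sided p).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDistributionError, FormatError
from .paths import CausalPath, PathSign, PathwayScoring

log = logging.getLogger(__name__)

DEFAULT_K = 700
DEFAULT_REPS = 1000

STAR_BANDS = ((0.000025, "****"), (0.00025, "***"), (0.0025, "**"), (0.025, "*"))


def stars_for_p(p: float) -> str:
    """Significance stars; strict inequality at each band boundary."""
    for bound, stars in STAR_BANDS:
        if p < bound:
            return stars
    return ""


@dataclass(frozen=True)
class NullDistribution:
    """Replicate fractions of a statistic over random gene lists.

    Replicates where the statistic is undefined (no signed path in the
    sampled list) are stored as NaN and excluded from testing.
    """

    replicate_fractions: tuple[float, ...]
    k: int
    reps: int
    seed: int
    statistic_label: str = ""

    def __post_init__(self) -> None:
        if len(self.replicate_fractions) != self.reps:
            raise ValueError("replicate count does not match reps")
        for f in self.replicate_fractions:
            if not math.isnan(f) and not (0.0 <= f <= 1.0):
                raise ValueError(f"replicate fraction outside [0, 1]: {f}")

    @property
    def valid(self) -> np.ndarray:
        arr = np.asarray(self.replicate_fractions, dtype=float)
        return arr[~np.isnan(arr)]

    @property
    def mean(self) -> float:
        return float(self.valid.mean())

    @property
    def sd(self) -> float:
        return float(self.valid.std(ddof=1))


def sample_null_fractions(universe: Sequence[str],
                          statistic: Callable[[list[str]], float],
                          k: int = DEFAULT_K,
                          reps: int = DEFAULT_REPS,
                          seed: int = 0,
                          statistic_label: str = "") -> NullDistribution:
    """Evaluate ``statistic`` on ``reps`` random lists of ``k`` genes.

    Lists are sampled without replacement from the (sorted) universe; the
    random stream is split per replicate index from the single seed, so the
    distribution is reproducible and order-independent.  The statistic must
    return a fraction in [0, 1], or NaN where undefined.
    """
    universe = sorted(universe)
    if len(universe) < k:
        raise ValueError(
            f"universe of {len(universe)} genes is smaller than k={k}")
    if reps < 2:
        raise ValueError(f"need at least 2 replicates, got {reps}")
    children = np.random.SeedSequence(seed).spawn(reps)
    fractions = []
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.choice(len(universe), size=k, replace=False)
        value = statistic([universe[i] for i in idx])
        value = float("nan") if value is None else float(value)
        fractions.append(value)
    n_nan = sum(1 for f in fractions if math.isnan(f))
    if n_nan:
        log.warning("%d/%d null replicates had an undefined statistic (%s)",
                    n_nan, reps, statistic_label or "unnamed")
    return NullDistribution(tuple(fractions), k=k, reps=reps, seed=seed,
                            statistic_label=statistic_label)


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed-vs-null comparison for one statistic."""

    observed: float
    null_mean: float
    null_sd: float
    t_statistic: float
    p_value: float
    stars: str
    n_valid: int
    method: str = "prediction"


def test_against_null(observed: float, null: NullDistribution,
                      method: str = "prediction") -> EnrichmentResult:
    """Two-sided t comparison of the observed fraction with the null.

    ``method="prediction"`` (default) scales by the null spread,
    ``sd * sqrt(1 + 1/n)``, so an observation drawn from the null itself is
    rejected at the nominal rate.  ``method="mean"`` is the naive one-sample
    t-test of the replicates against the observed value as hypothesised
    mean (anticonservative for this design; provided for comparison).
    Positive t means the observed fraction exceeds the null mean.
    """
    valid = null.valid
    n = valid.size
    if n < 2:
        raise DegenerateDistributionError(
            "null distribution has fewer than 2 valid replicates")
    mean = float(valid.mean())
    sd = float(valid.std(ddof=1))
    if sd == 0:
        raise DegenerateDistributionError(
            "null distribution has zero spread: every random list gave the "
            "same fraction; increase reps or check the statistic")
    if method == "prediction":
        t = (observed - mean) / (sd * math.sqrt(1.0 + 1.0 / n))
        p = float(2 * sps.t.sf(abs(t), df=n - 1))
    elif method == "mean":
        res = sps.ttest_1samp(valid, popmean=observed)
        t, p = float(-res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return EnrichmentResult(observed=float(observed), null_mean=mean,
                            null_sd=sd, t_statistic=float(t),
                            p_value=p, stars=stars_for_p(p),
                            n_valid=int(n), method=method)


def updown_path_fractions(paths: Iterable[CausalPath]
                          ) -> tuple[float, float] | None:
    """Fractions of activating (UP) and inhibiting (DOWN) paths.

    Considers only signed paths of positive length (zero-length self-paths
    and indeterminate paths are excluded).  Returns None when no signed
    path exists — the fractions are undefined, not zero.
    """
    n_act = n_inh = 0
    for p in paths:
        if p.length == 0:
            continue
        if p.sign is PathSign.ACTIVATING:
            n_act += 1
        elif p.sign is PathSign.INHIBITING:
            n_inh += 1
    total = n_act + n_inh
    if total == 0:
        return None
    return n_act / total, n_inh / total


# ---------------------------------------------------------------------------
# Gene-class input
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ("gene_symbol", "gene symbol", "gene", "symbol")
_ROLE_COLUMNS = ("role", "role in cancer", "gene_class", "class")


def read_gene_classes(source: Union[str, Path, TextIO]) -> dict[str, str]:
    """Read a gene-class CSV (curated cancer-gene dialect tolerated).

    Returns ``{gene: role}`` with roles normalised to ``oncogene`` / ``TSG``.
    Genes annotated with both roles are ambiguous and excluded (with a
    warning), matching the use of unambiguously classified genes only.
    """
    frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in frame.columns}
    gene_col = next((cols[c] for c in _GENE_COLUMNS if c in cols), None)
    role_col = next((cols[c] for c in _ROLE_COLUMNS if c in cols), None)
    if gene_col is None or role_col is None:
        raise FormatError(
            "gene-class file needs a gene column "
            f"({'/'.join(_GENE_COLUMNS)}) and a role column "
            f"({'/'.join(_ROLE_COLUMNS)})")
    classes: dict[str, str] = {}
    for _, row in frame.iterrows():
        gene = str(row[gene_col]).strip()
        role = str(row[role_col]).strip().lower()
        if not gene:
            continue
        is_onc = "oncogene" in role
        is_tsg = "tsg" in role or "suppressor" in role
        if is_onc and is_tsg:
            log.warning("gene %s has ambiguous role %r; excluded", gene, role)
            continue
        if is_onc:
            classes[gene] = "oncogene"
        elif is_tsg:
            classes[gene] = "TSG"
        else:
            log.warning("gene %s has unrecognised role %r; excluded", gene, role)
    return classes


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

def _row_seed(seed: int, index: int) -> int:
    return (seed * 10007 + index) % (2 ** 31)


def make_fraction_significant(scoring: PathwayScoring
                              ) -> Callable[[list[str]], float]:
    """Statistic: fraction of listed genes significantly close to >= 1 pathway."""
    def stat(genes: list[str]) -> float:
        elig = [g for g in genes if g in scoring.scores[next(iter(scoring.scores))]]
        if not elig:
            return float("nan")
        return sum(scoring.is_significant_anywhere(g) for g in elig) / len(elig)
    return stat


def make_fraction_direction(scoring: PathwayScoring, pathway: str,
                            direction: str) -> Callable[[list[str]], float]:
    """Statistic: among listed genes significantly close to ``pathway``,
    the pooled fraction of their paths that are activating (UP) or
    inhibiting (DOWN)."""
    def stat(genes: list[str]) -> float:
        pooled: list[CausalPath] = []
        byg = scoring.scores[pathway]
        for g in genes:
            s = byg.get(g)
            if s is None or not s.significant:
                continue
            pooled.extend(scoring.paths.get((g, pathway), ()))
        fr = updown_path_fractions(pooled)
        if fr is None:
            return float("nan")
        return fr[0] if direction == "UP" else fr[1]
    return stat


def enrichment_report(scoring: PathwayScoring,
                      classes: Mapping[str, str],
                      k: int = DEFAULT_K,
                      reps: int = DEFAULT_REPS,
                      seed: int = 0,
                      method: str = "prediction",
                      include_closeness: bool = True) -> pd.DataFrame:
    """Per (pathway, gene class, direction) comparison against random lists.

    For each class the report contains one CLOSE row (fraction of class
    genes significantly close to any pathway) when ``include_closeness``,
    and per pathway an UP and a DOWN row (fractions of activating/
    inhibiting paths from the class's significant genes).  Each row carries
    the observed fraction, the null mean/sd over ``reps`` random lists of
    ``k`` genes, and the t, p, stars of the comparison.
    """
    class_names = sorted(set(classes.values()))
    members = {c: sorted(g for g, r in classes.items() if r == c)
               for c in class_names}
    for cname, genes in members.items():
        if not genes:
            raise ValueError(f"gene class {cname!r} has no member genes")
    universe = scoring.universe
    rows = []
    row_index = 0
    specs: list[tuple[str, str, Callable[[list[str]], float]]] = []
    if include_closeness:
        specs.append(("ANY", "CLOSE", make_fraction_significant(scoring)))
    for pathway in scoring.pathways():
        for direction in ("UP", "DOWN"):
            specs.append((pathway, direction,
                          make_fraction_direction(scoring, pathway, direction)))

    for pathway, direction, stat in specs:
        label = f"{pathway}:{direction}"
        null = sample_null_fractions(universe, stat, k=k, reps=reps,
                                     seed=_row_seed(seed, row_index),
                                     statistic_label=label)
        row_index += 1
        for cname in class_names:
            observed = stat(members[cname])
            base = {"pathway": pathway, "gene_class": cname,
                    "direction": direction, "k": k, "reps": reps}
            if math.isnan(observed):
                log.warning("statistic %s undefined for class %s", label, cname)
                rows.append({**base, "observed": float("nan"),
                             "null_mean": null.mean, "null_sd": null.sd,
                             "t": float("nan"), "p": float("nan"), "stars": ""})
                continue
            res = test_against_null(observed, null, method=method)
            rows.append({**base, "observed": res.observed,
                         "null_mean": res.null_mean, "null_sd": res.null_sd,
                         "t": res.t_statistic, "p": res.p_value,
                         "stars": res.stars})
    return pd.DataFrame(rows, columns=["pathway", "gene_class", "direction",
                                       "observed", "null_mean", "null_sd",
                                       "t", "p", "stars", "k", "reps"])


def write_enrichment_tsv(report: pd.DataFrame, path: Union[str, Path]) -> None:
    report.to_csv(path, sep="\t", index=False)
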