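"""Donor-anchored percent-spliced-in (PSI) and ddCq relative expression.

PSI for a target acceptor at an anchored donor is
``inclusion / (inclusion + exclusion)`` where inclusion reads splice to the
target and exclusion reads splice to any competing acceptor of the same
donor.  A zero denominator gives an *undefined* PSI (``None``), never 0 or 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from crypticex.cryptic_discovery import JunctionIndex

logger = logging.getLogger(__name__)

POOL_COUNTS = "pool_counts"
MEAN_OF_SAMPLES = "mean_of_samples"


class TargetAbsentError(KeyError):
    """The requested target site is not part of the competition set."""


@dataclass
class CompetitionSet:
    """All acceptors (or donors) competing at one anchored splice site."""

    anchor: int
    strand: str
    anchored_on: str  # "donor" or "acceptor"
    sites: dict[int, dict[tuple[str, str], int]] = field(default_factory=dict)
    # sites: competing site -> {(sample_id, condition): count}

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for counts in self.sites.values():
            for (_s, cond) in counts:
                seen.setdefault(cond, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.sites)


def competing_junctions(index: JunctionIndex, donor: int) -> CompetitionSet:
    """All acceptors reachable from ``donor`` with their per-sample counts.

    An unknown donor yields an empty set with a warning (not an error)."""
    cset = CompetitionSet(anchor=donor, strand=index.strand, anchored_on="donor")
    acc_map = index.donor_to_acceptors.get(donor)
    if acc_map is None:
        logger.warning("donor %s not present in junction index", donor)
        return cset
    cset.sites = {a: dict(counts) for a, counts in acc_map.items()}
    return cset


def competing_donors(index: JunctionIndex, acceptor: int) -> CompetitionSet:
    """Symmetric, acceptor-anchored variant (competition among donors)."""
    cset = CompetitionSet(anchor=acceptor, strand=index.strand, anchored_on="acceptor")
    don_map = index.acceptor_to_donors.get(acceptor)
    if don_map is None:
        logger.warning("acceptor %s not present in junction index", acceptor)
        return cset
    cset.sites = {d: dict(counts) for d, counts in don_map.items()}
    return cset


@dataclass(frozen=True)
class PsiResult:
    """PSI of one target site at one anchor for one condition."""

    anchor: int
    target: int
    condition: str
    inclusion: int
    exclusion: int
    psi: Optional[float]
    n_samples: int
    pooling: str = POOL_COUNTS


def psi(
    cset: CompetitionSet,
    target: int,
    pooling: str = POOL_COUNTS,
) -> list[PsiResult]:
    """Per-condition PSI of ``target`` within the competition set.

    ``pool_counts`` sums counts across a condition's samples before taking
    the ratio; ``mean_of_samples`` averages per-sample PSI over samples with
    nonzero coverage.  A missing target raises :class:`TargetAbsentError`
    (distinct from an undefined PSI)."""
    if target not in cset.sites:
        raise TargetAbsentError(
            f"target site {target} absent from competition set at anchor {cset.anchor}"
        )
    if pooling not in (POOL_COUNTS, MEAN_OF_SAMPLES):
        raise ValueError(f"unknown pooling mode {pooling!r}")

    results: list[PsiResult] = []
    for cond in cset.conditions():
        samples = sorted(
            {s for counts in cset.sites.values() for (s, c) in counts if c == cond}
        )
        inc = sum(
            c for (s, cc), c in cset.sites.get(target, {}).items() if cc == cond
        )
        tot = 0
        for counts in cset.sites.values():
            tot += sum(c for (s, cc), c in counts.items() if cc == cond)
        exc = tot - inc
        if pooling == POOL_COUNTS:
            value = inc / tot if tot > 0 else None
        else:
            per_sample = []
            for s in samples:
                s_inc = cset.sites[target].get((s, cond), 0)
                s_tot = sum(
                    counts.get((s, cond), 0) for counts in cset.sites.values()
                )
                if s_tot > 0:
                    per_sample.append(s_inc / s_tot)
            value = sum(per_sample) / len(per_sample) if per_sample else None
        results.append(
            PsiResult(
                anchor=cset.anchor,
                target=target,
                condition=cond,
                inclusion=inc,
                exclusion=exc,
                psi=value,
                n_samples=len(samples),
                pooling=pooling,
            )
        )
    return results


def psi_for_condition(results: Sequence[PsiResult], condition: str) -> PsiResult:
    for r in results:
        if r.condition == condition:
            return r
    raise KeyError(f"no PSI result for condition {condition!r}")


def delta_psi(a: PsiResult, b: PsiResult) -> Optional[float]:
    """``psi(a) - psi(b)``; undefined PSI propagates as ``None``."""
    if a.anchor != b.anchor or a.target != b.target:
        raise ValueError(
            f"delta_psi across different junctions: "
            f"({a.anchor}->{a.target}) vs ({b.anchor}->{b.target})"
        )
    if a.psi is None or b.psi is None:
        return None
    return a.psi - b.psi


# ---------------------------------------------------------------------------
# ddCq relative expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionResult:
    sample_id: str
    condition: str
    gene: str
    dcq: float
    ddcq: float
    level: float


def relative_expression_ddcq(
    records: pd.DataFrame,
    calibrator: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Relative expression by the ddCq method, per target gene.

    ``records`` needs columns ``sample_id, condition, gene, cq_target,
    cq_reference``.  dCq = Cq_target - Cq_reference; ddCq subtracts the mean
    dCq of the calibrator condition; level = efficiency**(-ddCq).  Samples
    missing a reference Cq are dropped with a warning.
    """
    required = {"sample_id", "condition", "gene", "cq_target", "cq_reference"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    df = records.copy()
    bad = df["cq_reference"].isna() | df["cq_target"].isna()
    if bad.any():
        logger.warning("dropping %d Cq rows without target/reference Cq", int(bad.sum()))
        df = df[~bad]
    out_rows: list[ExpressionResult] = []
    for gene, sub in df.groupby("gene", sort=True):
        dcq = sub["cq_target"] - sub["cq_reference"]
        cal = dcq[sub["condition"] == calibrator]
        if cal.empty:
            raise ValueError(
                f"no calibrator-condition ({calibrator!r}) samples for gene {gene!r}"
            )
        cal_mean = cal.mean()
        for (_, row), d in zip(sub.iterrows(), dcq):
            ddcq = d - cal_mean
            out_rows.append(
                ExpressionResult(
                    sample_id=row["sample_id"],
                    condition=row["condition"],
                    gene=gene,
                    dcq=float(d),
                    ddcq=float(ddcq),
                    level=float(efficiency ** (-ddcq)),
                )
            )
    out = pd.DataFrame([r.__dict__ for r in out_rows])
    return out.sort_values(["gene", "condition", "sample_id"], kind="mergesort").reset_index(
        drop=True
    )


def geometric_mean(values: Sequence[float]) -> float:
    if not values:
        raise ValueError("geometric mean of empty sequence")
    return math.exp(sum(math.log(v) for v in values) / len(values))
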