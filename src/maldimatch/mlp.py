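"""tau-search mass matching and MLP (most-likely-peptide) protein assignment.

A deisotoped IMS monoisotopic mass is matched against LC-MS peptides by
comparing it with each peptide's singly protonated mass
``MH+ = neutral mass + 1.007276`` within a tolerance tau (default
+/-0.1 Da, the accuracy of the MALDI-TOF setup).  The search space is
restricted to the peptides classified to the cluster's condition: a
cluster occurring in the control-like tissue is only compared with
control-classified peptides, and vice versa.

Ambiguity among the resulting near-isobaric candidates is resolved by the
MLP score

    MLP = mu * |log2FC| / p

where mu is the peptide's mean LC-MS intensity across the replicates of
its condition, log2FC its fold change, and p its moderated p-value.  Two
observations motivate the score: peptides of relatively higher abundance
are preferentially detected by MALDI-TOF imaging, and a mass seen in a
condition-specific cluster should belong to a peptide confidently enriched
in that condition.  The candidate with the highest MLP wins; the higher
the score, the more likely the IMS mass belongs to that peptide's protein.
The absolute value keeps control-side scores positive so one orientation
serves both conditions (a ``signed`` mode evaluates the formula literally).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .deisotope import MonoisotopicEntry, MonoisotopicList
from .diffstats import P_FLOOR, PeptideTable
from .isotopes import PROTON_MASS


class MatchCandidate(NamedTuple):
    ims_mz: float
    sequence: str
    neutral_mass: float
    mh: float  # theoretical MH+
    delta: float  # ims_mz - mh
    protein: str
    mu: float
    log2fc: float
    p: float
    group: str


@dataclass
class MLPAssignment:
    ims_mz: float
    cluster: int
    candidate: MatchCandidate | None
    score: float
    runner_up_score: float
    ambiguous: bool
    status: str  # "assigned" | "unmatched"


def peptide_records(table: PeptideTable) -> pd.DataFrame:
    """Flatten a classified, tested PeptideTable into the match search space.

    One row per peptide with its sequence, neutral mass, protein, group
    label, moderated p, log2fc, and mu — the mean linear intensity in the
    peptide's own condition.
    """
    required = {"log2fc", "p", "group"}
    if not required <= set(table.stats.columns):
        raise ValueError("run moderated_ttest and fold_change_classify first")
    g0, g1 = table.group_names
    mu = np.where(
        table.stats["group"] == g1, table.stats[f"mu_{g1}"], table.stats[f"mu_{g0}"]
    )
    return pd.DataFrame(
        {
            "sequence": table.meta["Sequence"].to_numpy(),
            "mass": table.meta["Mass"].to_numpy(dtype=float),
            "protein": table.meta["Protein"].to_numpy(),
            "mu": mu,
            "log2fc": table.stats["log2fc"].to_numpy(),
            "p": table.stats["p"].to_numpy(),
            "group": table.stats["group"].to_numpy(),
        }
    )


def tau_search(
    mono: MonoisotopicList | Sequence[float] | np.ndarray,
    records: pd.DataFrame | PeptideTable,
    tau: float = 0.1,
    cluster_condition: str | None = None,
) -> list[tuple[float, list[MatchCandidate]]]:
    """Match IMS masses to peptide MH+ masses within ``|delta| <= tau``.

    ``cluster_condition`` restricts the search space to peptides classified
    to that condition (pass None to search all classified peptides).  Every
    IMS mass is reported, with an empty candidate list when nothing matches.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if isinstance(records, PeptideTable):
        records = peptide_records(records)
    if isinstance(mono, MonoisotopicList):
        ims_mzs = [e.mono_mz for e in mono.entries]
    else:
        ims_mzs = [float(m) for m in np.asarray(mono, dtype=float)]
    space = records
    if cluster_condition is not None:
        space = records[records["group"] == cluster_condition]
    mh = space["mass"].to_numpy(dtype=float) + PROTON_MASS
    order = np.argsort(mh, kind="stable")
    mh_sorted = mh[order]
    rows = space.iloc[order].reset_index(drop=True)
    out: list[tuple[float, list[MatchCandidate]]] = []
    eps = 1e-9  # keeps a delta exactly equal to tau inside despite float rounding
    for mz in ims_mzs:
        a = int(np.searchsorted(mh_sorted, mz - tau - eps, side="left"))
        b = int(np.searchsorted(mh_sorted, mz + tau + eps, side="right"))
        cands = []
        for i in range(a, b):
            if abs(mz - mh_sorted[i]) <= tau + eps:
                r = rows.iloc[i]
                cands.append(
                    MatchCandidate(
                        ims_mz=mz,
                        sequence=str(r["sequence"]),
                        neutral_mass=float(r["mass"]),
                        mh=float(mh_sorted[i]),
                        delta=float(mz - mh_sorted[i]),
                        protein=str(r["protein"]),
                        mu=float(r["mu"]),
                        log2fc=float(r["log2fc"]),
                        p=float(r["p"]),
                        group=str(r["group"]),
                    )
                )
        out.append((mz, cands))
    return out


def mlp_score(candidate: MatchCandidate | None = None, *, mu: float | None = None,
              log2fc: float | None = None, p: float | None = None, signed: bool = False) -> float:
    """MLP = mu * |log2FC| / p (signed mode omits the absolute value)."""
    if candidate is not None:
        mu, log2fc, p = candidate.mu, candidate.log2fc, candidate.p
    if mu is None or log2fc is None or p is None:
        raise ValueError("provide a candidate or mu, log2fc and p")
    p = max(float(p), P_FLOOR)
    fc = float(log2fc) if signed else abs(float(log2fc))
    if np.isnan(fc):
        return 0.0
    score = float(mu) * fc / p
    if np.isinf(score):  # extreme mu with a floored p can overflow
        return float(np.sign(score)) * np.finfo(float).max
    return score


def assign_proteins(
    candidates_per_mz: list[tuple[float, list[MatchCandidate]]],
    cluster: int = 0,
    ambiguity_ratio: float = 2.0,
    signed: bool = False,
) -> list[MLPAssignment]:
    """Pick the maximal-MLP candidate for every IMS mass.

    Ties are broken by larger mu, then smaller |mass delta|, then
    lexicographic protein accession.  An assignment is flagged ambiguous
    when the runner-up score is within ``ambiguity_ratio`` of the winner
    (the flag never changes the winner).  Masses without candidates are
    reported with status ``unmatched``.
    """
    out = []
    for mz, cands in candidates_per_mz:
        if not cands:
            out.append(MLPAssignment(mz, cluster, None, np.nan, np.nan, False, "unmatched"))
            continue
        scored = sorted(
            ((mlp_score(c, signed=signed), c) for c in cands),
            key=lambda sc: (-sc[0], -sc[1].mu, abs(sc[1].delta), sc[1].protein),
        )
        best_score, best = scored[0]
        runner = scored[1][0] if len(scored) > 1 else np.nan
        ambiguous = bool(
            len(scored) > 1 and best_score > 0 and scored[1][0] * ambiguity_ratio > best_score
        )
        out.append(MLPAssignment(mz, cluster, best, best_score, runner, ambiguous, "assigned"))
    return out


def assignments_frame(assignments: list[MLPAssignment]) -> pd.DataFrame:
    """Tabulate assignments (one row per IMS mass, unmatched included)."""
    rows = []
    for a in assignments:
        c = a.candidate
        rows.append(
            dict(
                ims_mz=a.ims_mz,
                cluster=a.cluster,
                status=a.status,
                sequence=c.sequence if c else "",
                protein=c.protein if c else "",
                mh=c.mh if c else np.nan,
                delta=c.delta if c else np.nan,
                mu=c.mu if c else np.nan,
                log2fc=c.log2fc if c else np.nan,
                p=c.p if c else np.nan,
                mlp=a.score,
                ambiguous=a.ambiguous,
            )
        )
    return pd.DataFrame(rows)


def cluster_report(assignments: list[MLPAssignment]) -> dict[int, pd.DataFrame]:
    """Per-cluster protein tables: each protein's best-scoring IMS mass.

    Suitable as the selection input for over-representation analysis.
    Clusters with zero matched masses yield an empty table with the full
    header.
    """
    df = assignments_frame(assignments)
    cols = ["protein", "ims_mz", "sequence", "mlp", "mu", "log2fc", "p"]
    out: dict[int, pd.DataFrame] = {}
    for c in sorted(df["cluster"].unique()):
        sub = df[(df["cluster"] == c) & (df["status"] == "assigned")]
        if not len(sub):
            out[int(c)] = pd.DataFrame(columns=cols)
            continue
        best = (
            sub.sort_values(["mlp", "mu"], ascending=False, kind="stable")
            .groupby("protein", as_index=False)
            .first()
        )
        out[int(c)] = best[cols].sort_values("mlp", ascending=False, kind="stable").reset_index(drop=True)
    return out
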