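"""Junction-based differential splicing between seasonal forms.

Percent spliced in (PSI) is estimated per sample from length-normalized
inclusion vs skipping junction counts. A census filter removes weakly
supported events (combined junction support < 20) and extreme-PSI events
(mean PSI outside (0.1, 0.9)); the PSI band is deliberately *not* applied
when testing for differential splicing, because an isoform may exist in only
one seasonal form (PSI 0 or 1 on one side). A splice site is called
differentially spliced (DS) at FDR < 0.05, and a gene is a DSG if it owns at
least one DS site; a DSG with several DS sites is represented by the site
with the largest |dPSI|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")


@dataclass
class SpliceEvent:
    """One alternative-splicing event with per-sample junction counts."""

    event_id: str
    gene_id: str
    etype: str
    li: int  # effective length of the inclusion junction set
    ls: int  # effective length of the skipping junction set
    inclusion: dict  # sample id -> count
    skipping: dict  # sample id -> count

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.etype!r}")
        if self.li < 1 or self.ls < 1:
            raise ValueError("effective lengths must be >= 1")
        for d in (self.inclusion, self.skipping):
            if any(v < 0 for v in d.values()):
                raise ValueError("junction counts must be nonnegative")


@dataclass
class DiffSpliceResult:
    event_id: str
    gene_id: str
    stage: str
    dpsi: float  # mean PSI(DS) - mean PSI(WS)
    p: float
    fdr: float = float("nan")


def compute_psi(i: int, s: int, li: int, ls: int) -> float:
    """Length-weighted PSI = (I/lI) / (I/lI + S/lS); undefined when I+S = 0."""
    if i < 0 or s < 0:
        raise ValueError("junction counts must be nonnegative")
    if li < 1 or ls < 1:
        raise ValueError("effective lengths must be >= 1")
    if i + s == 0:
        raise ValueError("PSI undefined for I + S = 0; treat sample as missing")
    wi = i / li
    ws = s / ls
    return wi / (wi + ws)


def psi_per_sample(event: SpliceEvent, samples) -> dict:
    """PSI for each sample with nonzero junction support."""
    out = {}
    for sid in samples:
        i = event.inclusion.get(sid, 0)
        s = event.skipping.get(sid, 0)
        if i + s > 0:
            out[sid] = compute_psi(i, s, event.li, event.ls)
    return out


def _junction_support_ok(event, samples, min_junction_sum, mode) -> bool:
    ti = sum(event.inclusion.get(s, 0) for s in samples)
    ts = sum(event.skipping.get(s, 0) for s in samples)
    if mode == "sum":
        return ti + ts >= min_junction_sum
    if mode == "each":
        return ti >= min_junction_sum and ts >= min_junction_sum
    raise ValueError(f"unknown support mode {mode!r}")


def census_filter(
    events,
    samples,
    min_junction_sum: int = 20,
    mode: str = "sum",
    psi_band: tuple[float, float] | None = (0.1, 0.9),
):
    """Keep events with combined junction support >= 20 and mid-range PSI.

    ``psi_band=None`` disables the strict mean-PSI band (used for the DS
    test, where one-form-exclusive isoforms must stay testable).
    """
    survivors = []
    for ev in events:
        if not _junction_support_ok(ev, samples, min_junction_sum, mode):
            continue
        if psi_band is not None:
            psis = list(psi_per_sample(ev, samples).values())
            if not psis:
                continue
            m = float(np.mean(psis))
            if not (psi_band[0] < m < psi_band[1]):
                continue
        survivors.append(ev)
    return survivors


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t test; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(nx + ny - 2), 1.0
        raise ZeroDivisionError("zero variance in both groups with unequal means")
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(1.0, p))


def ds_test(event: SpliceEvent, ws_samples, ds_samples, stage: str = "") -> DiffSpliceResult:
    """Test one event for differential splicing between forms.

    Welch's t on arcsine-sqrt transformed per-sample PSI. Degenerate case
    (zero variance in both groups): p = 1 if the means are equal, otherwise
    an exact two-proportion comparison (Fisher) on pooled junction counts.
    """
    psi_ws = psi_per_sample(event, ws_samples)
    psi_ds = psi_per_sample(event, ds_samples)
    if len(psi_ws) < 2 or len(psi_ds) < 2:
        raise ValueError(
            f"event {event.event_id}: need >= 2 supported samples per form"
        )
    ws = np.array(list(psi_ws.values()))
    ds = np.array(list(psi_ds.values()))
    dpsi = float(ds.mean() - ws.mean())
    tws = np.arcsin(np.sqrt(ws))
    tds = np.arcsin(np.sqrt(ds))
    if tws.var(ddof=1) == 0.0 and tds.var(ddof=1) == 0.0:
        if np.isclose(tws.mean(), tds.mean()):
            p = 1.0
        else:
            table = [
                [sum(event.inclusion.get(s, 0) for s in ws_samples),
                 sum(event.skipping.get(s, 0) for s in ws_samples)],
                [sum(event.inclusion.get(s, 0) for s in ds_samples),
                 sum(event.skipping.get(s, 0) for s in ds_samples)],
            ]
            p = float(stats.fisher_exact(table)[1])
    else:
        _, _, p = welch_t(tds, tws)
    return DiffSpliceResult(event.event_id, event.gene_id, stage, dpsi, p)


def diff_splicing(
    events,
    ws_samples,
    ds_samples,
    stage: str = "",
    min_junction_sum: int = 20,
    mode: str = "sum",
) -> list[DiffSpliceResult]:
    """Per-stage DS testing with BH FDR over all tested events.

    Applies the junction-support filter but not the PSI band; events with
    insufficient supported replicates are skipped with a logged reason.
    """
    from .diffexpr import bh_adjust

    all_samples = list(ws_samples) + list(ds_samples)
    results = []
    for ev in events:
        if not _junction_support_ok(ev, all_samples, min_junction_sum, mode):
            continue
        try:
            results.append(ds_test(ev, ws_samples, ds_samples, stage))
        except ValueError as exc:
            logger.info("skipping event: %s", exc)
    if results:
        adj = bh_adjust([r.p for r in results])
        for r, q in zip(results, adj):
            r.fdr = float(q)
    return results


def summarize_dsg(results, fdr: float = 0.05) -> pd.DataFrame:
    """Collapse DS events to genes: a gene is a DSG iff >= 1 event has
    FDR < ``fdr``; its representative dPSI is that of the significant event
    with maximum |dPSI| (ties: smaller p, then lexicographic event id)."""
    sig = [r for r in results if r.fdr < fdr]
    best: dict = {}
    for r in sig:
        cur = best.get(r.gene_id)
        key = (-abs(r.dpsi), r.p, r.event_id)
        if cur is None or key < (-abs(cur.dpsi), cur.p, cur.event_id):
            best[r.gene_id] = r
    rows = [
        {"gene": g, "event": r.event_id, "dpsi": r.dpsi, "p": r.p, "fdr": r.fdr}
        for g, r in sorted(best.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "event", "dpsi", "p", "fdr"])


def event_census(
    events,
    samples,
    gene_norm_means: dict | None = None,
    expressed_threshold: float = 0.1,
) -> dict:
    """Census of surviving events: per-type pooled counts, per-library counts
    (events with any junction support in that library), genes with >= 1
    event, and — when normalized gene means are supplied — the fraction of
    expressed genes (normalized mean > threshold) carrying >= 1 event."""
    by_type = {t: 0 for t in EVENT_TYPES}
    per_library: dict = {s: {t: 0 for t in EVENT_TYPES} for s in samples}
    genes = set()
    for ev in events:
        by_type[ev.etype] += 1
        genes.add(ev.gene_id)
        for s in samples:
            if ev.inclusion.get(s, 0) + ev.skipping.get(s, 0) > 0:
                per_library[s][ev.etype] += 1
    out = {
        "n_events": len(events),
        "by_type": by_type,
        "per_library": per_library,
        "n_genes_with_events": len(genes),
    }
    if gene_norm_means is not None:
        expressed = {g for g, m in gene_norm_means.items() if m > expressed_threshold}
        with_events = expressed & genes
        out["n_expressed_genes"] = len(expressed)
        out["fraction_expressed_genes_with_event"] = (
            len(with_events) / len(expressed) if expressed else 0.0
        )
    return out


def events_to_frame(events, samples) -> pd.DataFrame:
    """Tidy junction table: one row per (event, sample)."""
    rows = []
    for ev in events:
        for s in samples:
            rows.append(
                {
                    "event": ev.event_id, "gene": ev.gene_id, "type": ev.etype,
                    "sample": s, "I": ev.inclusion.get(s, 0),
                    "S": ev.skipping.get(s, 0), "lI": ev.li, "lS": ev.ls,
                }
            )
    return pd.DataFrame(rows, columns=["event", "gene", "type", "sample", "I", "S", "lI", "lS"])


def frame_to_events(df: pd.DataFrame) -> list[SpliceEvent]:
    events = []
    for (eid, gid, etype, li, ls), grp in df.groupby(
        ["event", "gene", "type", "lI", "lS"], sort=True
    ):
        events.append(
            SpliceEvent(
                event_id=eid, gene_id=gid, etype=etype, li=int(li), ls=int(ls),
                inclusion=dict(zip(grp["sample"], grp["I"].astype(int))),
                skipping=dict(zip(grp["sample"], grp["S"].astype(int))),
            )
        )
    events.sort(key=lambda e: e.event_id)
    return events


def results_to_frame(results) -> pd.DataFrame:
    """Results table using rMATS-style column names for familiarity."""
    rows = [
        {
            "ID": r.event_id, "GeneID": r.gene_id, "stage": r.stage,
            "IncLevelDifference": r.dpsi, "PValue": r.p, "FDR": r.fdr,
        }
        for r in sorted(results, key=lambda r: r.event_id)
    ]
    return pd.DataFrame(
        rows, columns=["ID", "GeneID", "stage", "IncLevelDifference", "PValue", "FDR"]
    )
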