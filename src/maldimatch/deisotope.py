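"""Co-localization-aware deisotoping of cluster-wise peak lists.

Overlapping isotope envelopes are the central obstacle to identifying
peptides in MALDI imaging data: envelopes of different peptides interleave
on the m/z axis.  Because all isotope peaks of one peptide share the same
spatial distribution, working cluster-by-cluster (after segmentation) and
requiring candidate isotope peaks to be co-localized with their
monoisotopic peak separates overlaps spatially rather than algebraically.

An envelope is grown greedily from each unconsumed peak, ascending in m/z:
peak q joins the envelope anchored at mono mass m when

1. ``|q.mz - (m + k * 1.00235)| <= mz_tol`` (default 0.15 Da) for the next
   isotope index k,
2. q's intensity is within a factor ``1 +/- intensity_tol`` (default 50%)
   of the averagine-expected intensity for isotope k given mono mass m,
3. the Pearson correlation of q's ion image with the mono peak's ion image
   is at least ``coloc_min`` (default 0.7).

Charge is fixed at 1+ (MALDI produces singly charged peptide ions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .ims import IMSDataset
from .isotopes import ISOTOPE_SPACING, envelope_ratios
from .segmentation import SegmentationResult

logger = logging.getLogger(__name__)


@dataclass
class DeisotopeParams:
    mz_tol: float = 0.15  # Da window around the expected isotope position
    intensity_tol: float = 0.5  # relative deviation allowed from the averagine expectation
    coloc_min: float = 0.7  # minimum Pearson r between member and mono ion images
    coloc_mode: str = "correlation"  # or "co-membership": cluster membership suffices
    max_isotopes: int = 6
    gap_tol: float = 0.02  # Da; m/z gap that separates cluster-level peak groups
    min_support: float = 0.05  # fraction of cluster pixels a peak must appear in
    centroid_sd: float = 0.04  # Da; centroid scatter of one true peak (+/-0.1 ~ 2.5 sigma)
    dedup_tol: float = 0.1  # Da tolerance for pooling unique monoisotopic masses

    def validate(self) -> None:
        if self.mz_tol <= 0 or self.intensity_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 < self.coloc_min <= 1):
            raise ValueError(f"coloc_min must be in (0, 1], got {self.coloc_min}")
        if self.coloc_mode not in ("correlation", "co-membership"):
            raise ValueError(f"unknown coloc_mode {self.coloc_mode!r}")


@dataclass
class ClusterPeakSet:
    """Cluster-level peak list: m/z, mean in-cluster intensity, ion images.

    ``images[i]`` is peak i's per-pixel intensity vector over the cluster's
    pixels; peaks are sorted by m/z.
    """

    cluster_id: int
    mz: np.ndarray
    intensity: np.ndarray
    images: np.ndarray  # (n_peaks, n_cluster_pixels)

    def __post_init__(self):
        if len(self.mz) > 1 and np.any(np.diff(self.mz) < 0):
            raise ValueError("cluster peaks must be sorted by m/z")
        if len(self.mz) and not np.all(np.isfinite(self.images)):
            raise ValueError("ion-image vectors must be finite")

    def __len__(self) -> int:
        return len(self.mz)


class MonoisotopicEntry(NamedTuple):
    mono_mz: float
    cluster: int
    intensity: float  # summed envelope intensity
    members: tuple[float, ...]  # member peak m/z values, mono first


@dataclass
class MonoisotopicList:
    entries: list[MonoisotopicEntry]
    unassigned: list[float] = field(default_factory=list)

    @property
    def mono_mzs(self) -> np.ndarray:
        return np.array([e.mono_mz for e in self.entries])

    def n_peaks(self) -> int:
        return sum(len(e.members) for e in self.entries) + len(self.unassigned)


def colocalization(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Pearson correlation of two ion images over the same pixel set."""
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("ion images must cover the same pixel set")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance ion image: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _split_collided(mz: np.ndarray, w: np.ndarray, centroid_sd: float) -> list[tuple[int, int]]:
    """Split a sorted m/z sample group into unimodal sub-peaks.

    Peaks of two different peptides closer than the gap threshold merge
    into one sample group; their centroid scatter then exceeds what a
    single peak can produce.  Groups whose weighted SD exceeds
    ``1.5 * centroid_sd`` are split by weighted 1-D 2-means, accepted when
    the component means separate by at least ``2.5 * centroid_sd``, and
    recursed.  Collisions closer than that are genuinely unresolvable at
    the instrument's accuracy and stay merged.
    """
    out: list[tuple[int, int]] = []

    def rec(lo: int, hi: int) -> None:
        m, ww = mz[lo:hi], w[lo:hi]
        mean = np.average(m, weights=ww)
        sd = float(np.sqrt(np.average((m - mean) ** 2, weights=ww)))
        if hi - lo < 8 or sd <= 1.5 * centroid_sd:
            out.append((lo, hi))
            return
        c1, c2 = float(m[0]), float(m[-1])
        for _ in range(50):
            left = m <= (c1 + c2) / 2.0
            if not left.any() or left.all():
                break
            n1 = float(np.average(m[left], weights=ww[left]))
            n2 = float(np.average(m[~left], weights=ww[~left]))
            if abs(n1 - c1) < 1e-9 and abs(n2 - c2) < 1e-9:
                c1, c2 = n1, n2
                break
            c1, c2 = n1, n2
        if c2 - c1 >= 2.5 * centroid_sd:
            split = lo + int(np.searchsorted(m, (c1 + c2) / 2.0))
            if lo < split < hi:
                rec(lo, split)
                rec(split, hi)
                return
        out.append((lo, hi))

    if len(mz):
        rec(0, len(mz))
    return out


def build_cluster_peaks(
    ds: IMSDataset,
    labels: np.ndarray,
    cluster_id: int,
    params: DeisotopeParams | None = None,
) -> ClusterPeakSet:
    """Collapse the raw per-pixel peaks of one cluster into a cluster peak list.

    Raw m/z values from all in-cluster pixels are pooled, sorted, and split
    into groups wherever consecutive values differ by more than ``gap_tol``
    (centroid scatter within one true peak is dense; distinct peaks are
    ~1 Da apart).  Groups seen in fewer than ``min_support`` of the
    cluster's pixels are discarded as noise.  Each surviving group yields
    one cluster peak: intensity-weighted mean m/z, mean per-pixel
    intensity, and its ion-image vector over the cluster pixels.
    """
    params = params or DeisotopeParams()
    pix = np.flatnonzero(np.asarray(labels) == cluster_id)
    if not len(pix):
        raise ValueError(f"cluster {cluster_id} has no pixels")
    all_mz, all_int, all_pix = [], [], []
    for j, p in enumerate(pix):
        m = ds.mzs[p]
        if len(m):
            all_mz.append(m)
            all_int.append(ds.intensities[p])
            all_pix.append(np.full(len(m), j))
    if not all_mz:
        return ClusterPeakSet(cluster_id, np.zeros(0), np.zeros(0), np.zeros((0, len(pix))))
    mz = np.concatenate(all_mz)
    inten = np.concatenate(all_int)
    pixel = np.concatenate(all_pix)
    order = np.argsort(mz, kind="stable")
    mz, inten, pixel = mz[order], inten[order], pixel[order]
    breaks = np.flatnonzero(np.diff(mz) > params.gap_tol) + 1
    starts = np.concatenate([[0], breaks])
    stops = np.concatenate([breaks, [len(mz)]])
    min_pixels = max(1, int(np.ceil(params.min_support * len(pix))))
    out_mz, out_int, out_img = [], [], []
    for a0, b0 in zip(starts, stops):
        for da, db in _split_collided(mz[a0:b0], inten[a0:b0], params.centroid_sd):
            a, b = a0 + da, a0 + db
            seg_pix = pixel[a:b]
            if len(np.unique(seg_pix)) < min_pixels:
                continue
            w = inten[a:b]
            out_mz.append(float(np.average(mz[a:b], weights=w)))
            out_int.append(float(w.sum() / len(pix)))
            img = np.zeros(len(pix))
            np.add.at(img, seg_pix, w)
            out_img.append(img)
    if not out_mz:
        return ClusterPeakSet(cluster_id, np.zeros(0), np.zeros(0), np.zeros((0, len(pix))))
    order = np.argsort(out_mz)
    return ClusterPeakSet(
        cluster_id,
        np.array(out_mz)[order],
        np.array(out_int)[order],
        np.stack(out_img)[order],
    )


def _colocalized(peaks: ClusterPeakSet, i: int, j: int, params: DeisotopeParams) -> bool:
    if params.coloc_mode == "co-membership":
        return True
    try:
        r = colocalization(peaks.images[i], peaks.images[j])
    except ValueError:
        return False  # undefined correlation => not co-localized
    return r >= params.coloc_min


def deisotope_cluster(peaks: ClusterPeakSet, params: DeisotopeParams | None = None) -> MonoisotopicList:
    """Greedy ascending-m/z envelope assembly with no peak reuse.

    Each unconsumed peak in turn anchors a candidate envelope; successive
    isotope positions are filled while a spacing-, intensity- and
    co-localization-consistent unconsumed peak exists.  Singleton peaks
    become their own monoisotopic entries.  An empty peak set yields an
    empty list.
    """
    params = params or DeisotopeParams()
    params.validate()
    n = len(peaks)
    consumed = np.zeros(n, dtype=bool)
    entries: list[MonoisotopicEntry] = []
    for i in range(n):
        if consumed[i]:
            continue
        consumed[i] = True
        mono = float(peaks.mz[i])
        ratios = envelope_ratios(mono, params.max_isotopes)
        members = [i]
        for k in range(1, params.max_isotopes):
            expect_mz = mono + k * ISOTOPE_SPACING
            cand = np.flatnonzero(
                ~consumed & (np.abs(peaks.mz - expect_mz) <= params.mz_tol)
            )
            if not len(cand):
                break
            expect_int = peaks.intensity[i] * ratios[k]
            ok = []
            for j in cand:
                dev = abs(peaks.intensity[j] - expect_int)
                if dev <= params.intensity_tol * expect_int and _colocalized(peaks, i, int(j), params):
                    ok.append(int(j))
            if not ok:
                break
            j = min(ok, key=lambda jj: abs(peaks.mz[jj] - expect_mz))
            consumed[j] = True
            members.append(j)
        entries.append(
            MonoisotopicEntry(
                mono_mz=mono,
                cluster=peaks.cluster_id,
                intensity=float(peaks.intensity[members].sum()),
                members=tuple(float(peaks.mz[m]) for m in members),
            )
        )
    return MonoisotopicList(entries)


def deisotope_exhaustive(peaks: ClusterPeakSet, params: DeisotopeParams | None = None) -> MonoisotopicList:
    """Exhaustive envelope-partition search for small peak sets.

    Enumerates all valid envelope partitions (same membership rules as the
    greedy pass) and returns one maximizing the number of explained peaks,
    i.e. peaks placed in envelopes of size >= 2; among maxima, the one whose
    anchors are lexicographically earliest in m/z order.  Intended as a
    reference for instances of ~30 peaks or fewer.
    """
    params = params or DeisotopeParams()
    params.validate()
    n = len(peaks)
    if n > 30:
        raise ValueError("exhaustive mode is limited to 30 peaks")

    best: tuple[int, list[list[int]]] | None = None

    def extensions(anchor: int, members: list[int], consumed: set[int]) -> list[int]:
        k = len(members)
        mono = float(peaks.mz[anchor])
        expect_mz = mono + k * ISOTOPE_SPACING
        expect_int = peaks.intensity[anchor] * envelope_ratios(mono, k + 1)[k]
        out = []
        for j in range(n):
            if j in consumed:
                continue
            if abs(peaks.mz[j] - expect_mz) > params.mz_tol:
                continue
            if abs(peaks.intensity[j] - expect_int) > params.intensity_tol * expect_int:
                continue
            if not _colocalized(peaks, anchor, j, params):
                continue
            out.append(j)
        return out

    def rec(consumed: set[int], envelopes: list[list[int]], explained: int) -> None:
        nonlocal best
        free = [i for i in range(n) if i not in consumed]
        if not free:
            if best is None or explained > best[0]:
                best = (explained, [list(e) for e in envelopes])
            return
        i = free[0]

        def grow(members: list[int]) -> None:
            nonlocal best
            if len(members) >= params.max_isotopes:
                finish(members)
                return
            exts = extensions(i, members, consumed | set(members))
            finish(members)  # stopping here is always a valid envelope
            for j in exts:
                grow(members + [j])

        def finish(members: list[int]) -> None:
            gain = len(members) if len(members) >= 2 else 0
            rec(consumed | set(members), envelopes + [members], explained + gain)

        grow([i])

    rec(set(), [], 0)
    assert best is not None
    entries = []
    for members in best[1]:
        entries.append(
            MonoisotopicEntry(
                mono_mz=float(peaks.mz[members[0]]),
                cluster=peaks.cluster_id,
                intensity=float(peaks.intensity[members].sum()),
                members=tuple(float(peaks.mz[m]) for m in members),
            )
        )
    entries.sort(key=lambda e: e.mono_mz)
    return MonoisotopicList(entries)


def deisotope_all(
    ds: IMSDataset,
    seg: SegmentationResult | np.ndarray,
    k: int | None = None,
    params: DeisotopeParams | None = None,
) -> tuple[dict[int, MonoisotopicList], MonoisotopicList]:
    """Deisotope every cluster and pool a deduplicated unique mass list.

    Returns per-cluster monoisotopic lists plus a pooled list in which
    monoisotopic masses from different clusters are merged when within
    ``dedup_tol`` (default +/-0.1 Da) of an already-kept mass.
    """
    params = params or DeisotopeParams()
    if isinstance(seg, SegmentationResult):
        if k is None:
            raise ValueError("k is required when passing a SegmentationResult")
        labels = seg.labels_at(k)
    else:
        labels = np.asarray(seg)
    per_cluster: dict[int, MonoisotopicList] = {}
    for c in np.unique(labels):
        peak_set = build_cluster_peaks(ds, labels, int(c), params)
        per_cluster[int(c)] = deisotope_cluster(peak_set, params)
        logger.info("cluster %d: %d peaks -> %d monoisotopic entries", c, len(peak_set), len(per_cluster[int(c)].entries))
    pooled_entries: list[MonoisotopicEntry] = []
    kept_mz: list[float] = []
    for c in sorted(per_cluster):
        for e in sorted(per_cluster[c].entries, key=lambda e: e.mono_mz):
            if any(abs(e.mono_mz - m) <= params.dedup_tol for m in kept_mz):
                continue
            kept_mz.append(e.mono_mz)
            pooled_entries.append(e)
    pooled = MonoisotopicList(sorted(pooled_entries, key=lambda e: e.mono_mz))
    logger.info("pooled unique deisotoped masses: %d", len(pooled.entries))
    return per_cluster, pooled


def export_monoisotopic_list(entries: MonoisotopicList | list[MonoisotopicEntry], path) -> None:
    """Write entries as TSV (mono_mz, cluster, intensity, n_member_peaks)."""
    if isinstance(entries, MonoisotopicList):
        entries = entries.entries
    with open(path, "w") as fh:
        fh.write("mono_mz\tcluster\tintensity\tn_member_peaks\n")
        for e in entries:
            fh.write(f"{e.mono_mz!r}\t{e.cluster}\t{e.intensity!r}\t{len(e.members)}\n")
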