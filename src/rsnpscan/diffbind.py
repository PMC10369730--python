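"""Differential transcription-factor binding scoring of SNPs.

For a SNP and a PWM of length m, every window (offset x strand) covering the
variant position is scored with the PWM log-odds on the sequence carrying a
given allele; the binding score of an allele is the maximum over all such
windows. The differential binding score D is the difference between the
wild-type (ref) and alternative (alt) allele scores — the log-odds ratio of
the two binding affinities. Under a panel of null SNPs, D per motif is well
described by a zero-centered Laplace distribution; its scale b is estimated
per motif as mean(|D|) (the Laplace MLE), and the differential-binding
p-value is the two-sided tail p = exp(-|D| / b).

Per-allele binding p-values come from the exact distribution of the window
score for an i.i.d. background sequence, computed by dynamic-programming
convolution over motif positions with scores discretized to a fixed bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .genome import Genome, encode
from .motifs import PWM, NEG_SENTINEL

#: sentinel score for windows that contain non-ACGT bases
_NOSCORE = -np.inf


class UncalibratedMotifError(RuntimeError):
    """A motif without a fitted null model reached the scanning stage."""


@dataclass
class ScoreDistribution:
    """Discrete distribution of the PWM window score under background.

    Support is stored as integer multiples of ``bin`` (bits).
    """

    support: np.ndarray  # ascending ints, units of `bin`
    probs: np.ndarray
    bin: float

    def __post_init__(self) -> None:
        # tail[i] = P(S >= support[i])
        self._tail = np.cumsum(self.probs[::-1])[::-1]

    def sf(self, score: float) -> float:
        """P(S >= score); evaluated on the binned support."""
        target = int(round(score / self.bin))
        idx = np.searchsorted(self.support, target, side="left")
        return float(self._tail[idx]) if idx < len(self.support) else 0.0

    def sf_many(self, scores: np.ndarray) -> np.ndarray:
        """Vectorized tail probabilities for an array of scores."""
        targets = np.round(np.asarray(scores) / self.bin).astype(np.int64)
        idx = np.searchsorted(self.support, targets, side="left")
        out = np.zeros(len(targets))
        inside = idx < len(self.support)
        out[inside] = self._tail[idx[inside]]
        return out

    @property
    def min_score(self) -> float:
        return float(self.support[0] * self.bin)

    @property
    def max_score(self) -> float:
        return float(self.support[-1] * self.bin)


@dataclass
class MotifNullModel:
    """Per-motif calibration: Laplace scale of null D + background score dist."""

    motif_id: str
    scale: float
    n_null: int
    score_dist: ScoreDistribution
    calibrated: bool = True


@dataclass
class DiffBindResult:
    """Per SNP x motif differential-binding record."""

    snp_id: str
    motif_id: str
    score_ref: float
    score_alt: float
    D: float
    p_bind_ref: float
    p_bind_alt: float
    best_offset: int
    best_strand: str
    p_diff: float | None = None


def score_distribution(pwm: PWM, background: np.ndarray | None = None,
                       bin: float = 0.01) -> ScoreDistribution:
    """Exact window-score distribution under an i.i.d. background sequence.

    Position-wise convolution on a score lattice of width ``bin`` bits.
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    bg = pwm.background if background is None else np.asarray(background, float)
    # integer lattice scores per position/base
    lat = np.round(pwm.logodds / bin).astype(np.int64)
    lo = int(lat.min(axis=1).sum())
    hi = int(lat.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # probabilities of partial sums; track current offset range
    cur = np.array([1.0])
    cur_lo = 0
    for p in range(len(pwm)):
        width = len(cur) + int(lat[p].max() - lat[p].min())
        nxt = np.zeros(width)
        nxt_lo = cur_lo + int(lat[p].min())
        for b in range(4):
            shift = int(lat[p, b]) - int(lat[p].min())
            nxt[shift:shift + len(cur)] += bg[b] * cur
        cur, cur_lo = nxt, nxt_lo
    pmf[cur_lo - lo: cur_lo - lo + len(cur)] = cur
    support = np.arange(lo, hi + 1)
    keep = pmf > 0
    return ScoreDistribution(support=support[keep], probs=pmf[keep], bin=bin)


def binding_pvalue(score: float, dist: ScoreDistribution) -> float:
    """Tail probability P(S >= score) of the background score distribution."""
    return dist.sf(score)


def _window_scores(codes: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Score every length-m window of an encoded sequence; -inf if any N."""
    m = logodds.shape[0]
    if len(codes) < m:
        return np.empty(0)
    win = sliding_window_view(codes, m)  # (n_windows, m)
    valid = (win >= 0).all(axis=1)
    safe = np.where(win >= 0, win, 0)
    scores = logodds[np.arange(m), safe].sum(axis=1)
    scores[~valid] = _NOSCORE
    return scores


def max_binding_score(genome: Genome, chrom: str, pos: int, allele: str,
                      pwm: PWM) -> tuple[float, int, str]:
    """Maximal PWM score over all windows covering a substituted allele.

    ``pos`` is 1-based. Both strands are scanned (reverse strand via the
    reverse-complemented matrix). Ties go to the smaller offset, then '+'.
    Returns (score, best 0-based window start, best strand); score is -inf
    when no window fits within the chromosome.
    """
    m = len(pwm)
    p0 = pos - 1
    clen = genome.length(chrom)
    if not (0 <= p0 < clen):
        raise ValueError(f"position {pos} outside {chrom}")
    lo = max(0, p0 - m + 1)
    hi = min(clen, p0 + m)          # region covering all candidate windows
    if hi - lo < m:
        return (_NOSCORE, -1, "+")
    seq = genome.fetch(chrom, lo, hi)
    codes = encode(seq)
    codes[p0 - lo] = "ACGT".index(allele.upper())
    fwd = _window_scores(codes, pwm.logodds)
    # reverse-strand score of a window == forward score under the
    # reverse-complemented matrix
    rc_logodds = pwm.logodds[::-1, ::-1]
    rev = _window_scores(codes, rc_logodds)
    # candidate windows must cover p0: offsets lo..p0 (0-based absolute)
    best_score, best_off, best_strand = _NOSCORE, -1, "+"
    for i in range(len(fwd)):
        off = lo + i
        if off > p0 or off + m <= p0:
            continue
        for strand, s in (("+", fwd[i]), ("-", rev[i])):
            if s > best_score:
                best_score, best_off, best_strand = s, off, strand
    return (float(best_score), best_off, best_strand)


def batch_max_scores(codes: np.ndarray, positions: np.ndarray,
                     alleles: np.ndarray, pwm: PWM) -> np.ndarray:
    """Max window scores for many (position, allele) substitutions at once.

    ``codes`` is the encoded chromosome, ``positions`` 0-based SNP
    positions, ``alleles`` integer base codes to substitute. Returns the
    per-SNP maximum over all covering windows and both strands; -inf where
    no window fits.
    """
    m = len(pwm)
    n = len(positions)
    rel = np.arange(-m + 1, m)
    idx = positions[:, None] + rel[None, :]
    valid = (idx >= 0) & (idx < len(codes))
    local = np.where(valid, codes[np.clip(idx, 0, len(codes) - 1)], -1)
    local[:, m - 1] = alleles
    lo_f = pwm.logodds
    lo_r = pwm.logodds[::-1, ::-1]
    best = np.full(n, _NOSCORE)
    pos_idx = np.arange(m)
    for j in range(m):          # window starting at relative offset j-m+1
        win = local[:, j:j + m]
        ok = (win >= 0).all(axis=1)
        safe = np.where(win >= 0, win, 0)
        sf = lo_f[pos_idx, safe].sum(axis=1)
        sr = lo_r[pos_idx, safe].sum(axis=1)
        s = np.maximum(sf, sr)
        s[~ok] = _NOSCORE
        best = np.maximum(best, s)
    return best


def batch_diff_scores(genome: Genome, chrom: str, positions: np.ndarray,
                      refs: np.ndarray, alts: np.ndarray,
                      pwm: PWM) -> np.ndarray:
    """Differential binding scores D for many SNPs against one motif.

    Vectorized counterpart of :func:`diff_binding_score` (scores only; no
    per-allele p-values or offsets). NaN marks unscoreable SNPs.
    """
    codes = encode(genome.fetch(chrom, 0, genome.length(chrom)))
    s_ref = batch_max_scores(codes, positions, refs, pwm)
    s_alt = batch_max_scores(codes, positions, alts, pwm)
    d = s_ref - s_alt
    d[~np.isfinite(s_ref) | ~np.isfinite(s_alt)] = np.nan
    return d


def diff_binding_score(genome: Genome, snp, pwm: PWM,
                       dist: ScoreDistribution | None = None,
                       check_ref: bool = True) -> DiffBindResult | None:
    """Differential binding score D = score(ref) - score(alt) for one SNP.

    Returns None (with a warning) for non-SNV records, for ref alleles that
    do not match the genome, and for SNPs too close to a contig end for any
    window to fit.
    """
    ref, alt = snp.ref.upper(), snp.alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        warnings.warn(f"{snp.rsid}: not a biallelic SNV ({ref}>{alt}), skipped")
        return None
    if check_ref:
        gbase = genome.base(snp.chrom, snp.pos - 1)
        if gbase != ref:
            warnings.warn(f"{snp.rsid}: ref allele {ref} does not match "
                          f"genome base {gbase}, skipped")
            return None
    s_ref, off, strand = max_binding_score(genome, snp.chrom, snp.pos, ref, pwm)
    s_alt, _, _ = max_binding_score(genome, snp.chrom, snp.pos, alt, pwm)
    if not np.isfinite(s_ref) or not np.isfinite(s_alt):
        warnings.warn(f"{snp.rsid}: no scoreable window for motif {pwm.id}, "
                      "skipped")
        return None
    if dist is None:
        dist = score_distribution(pwm)
    return DiffBindResult(
        snp_id=snp.rsid, motif_id=pwm.id,
        score_ref=s_ref, score_alt=s_alt, D=s_ref - s_alt,
        p_bind_ref=binding_pvalue(s_ref, dist),
        p_bind_alt=binding_pvalue(s_alt, dist),
        best_offset=off, best_strand=strand,
    )


def estimate_scale(pwm: PWM, genome: Genome, null_snps: Iterable,
                   min_scoreable: int = 100,
                   dist: ScoreDistribution | None = None) -> MotifNullModel:
    """Fit the per-motif Laplace scale b = mean(|D|) on a null SNP panel.

    A motif with fewer scoreable null SNPs than ``min_scoreable``, or with
    b = 0 (e.g. a uniform matrix), is flagged uncalibrated and excluded
    from scanning.
    """
    if dist is None:
        dist = score_distribution(pwm)
    snps = list(null_snps)
    base = {b: i for i, b in enumerate("ACGT")}
    keep = [s for s in snps
            if len(s.ref) == 1 and len(s.alt) == 1
            and s.ref.upper() in base and s.alt.upper() in base]
    abs_d = np.empty(0)
    if keep:
        chroms = {s.chrom for s in keep}
        parts = []
        for chrom in sorted(chroms):
            sub = [s for s in keep if s.chrom == chrom]
            pos = np.array([s.pos - 1 for s in sub])
            refs = np.array([base[s.ref.upper()] for s in sub])
            alts = np.array([base[s.alt.upper()] for s in sub])
            seq = encode(genome.fetch(chrom, 0, genome.length(chrom)))
            match = seq[pos] == refs
            d = batch_diff_scores(genome, chrom, pos[match], refs[match],
                                  alts[match], pwm)
            parts.append(d[np.isfinite(d)])
        abs_d = np.abs(np.concatenate(parts)) if parts else np.empty(0)
    n = len(abs_d)
    if n < min_scoreable:
        warnings.warn(f"motif {pwm.id}: only {n} scoreable null SNPs "
                      f"(< {min_scoreable}), motif uncalibrated")
        return MotifNullModel(pwm.id, scale=0.0, n_null=n, score_dist=dist,
                              calibrated=False)
    b = float(np.mean(abs_d))
    if b <= 0:
        warnings.warn(f"motif {pwm.id}: degenerate null (all D = 0), "
                      "motif uncalibrated")
        return MotifNullModel(pwm.id, scale=0.0, n_null=n, score_dist=dist,
                              calibrated=False)
    return MotifNullModel(pwm.id, scale=b, n_null=n, score_dist=dist)


def diff_binding_pvalue(D: float, model: MotifNullModel) -> float:
    """Two-sided Laplace tail p = exp(-|D| / b); p in (0, 1]."""
    if model.scale <= 0:
        raise ValueError(f"motif {model.motif_id}: nonpositive scale")
    return float(np.exp(-abs(D) / model.scale))


def scan_snps(snps: Sequence, pwms: Sequence[PWM], genome: Genome,
              null_models: dict[str, MotifNullModel],
              p_bind_max: float = 0.5,
              p_diff_max: float = 0.001) -> list[DiffBindResult]:
    """Scan SNP x motif pairs; emit those passing both p-value filters.

    A pair passes when at least one allele looks like a binding site
    (min(p_bind_ref, p_bind_alt) <= p_bind_max — so both loss and gain of
    binding are detectable) and the differential-binding p-value is at most
    ``p_diff_max``. A SNP is an rSNP iff it appears in >= 1 emitted pair.
    Output is sorted by (snp id, p_diff). Scoring is vectorized per motif;
    the best window/strand of each emitted pair is recovered individually.
    """
    for pwm in pwms:
        model = null_models.get(pwm.id)
        if model is None or not model.calibrated:
            raise UncalibratedMotifError(
                f"motif {pwm.id} has no calibrated null model")

    base_idx = {b: i for i, b in enumerate("ACGT")}
    usable = []
    for snp in snps:
        ref, alt = snp.ref.upper(), snp.alt.upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in base_idx \
                or alt not in base_idx:
            warnings.warn(f"{snp.rsid}: not a biallelic SNV "
                          f"({snp.ref}>{snp.alt}), skipped")
            continue
        if genome.base(snp.chrom, snp.pos - 1) != ref:
            warnings.warn(f"{snp.rsid}: ref allele does not match genome, "
                          "skipped")
            continue
        usable.append(snp)

    results: list[DiffBindResult] = []
    by_chrom: dict[str, list] = {}
    for snp in usable:
        by_chrom.setdefault(snp.chrom, []).append(snp)
    for chrom, chrom_snps in sorted(by_chrom.items()):
        codes = encode(genome.fetch(chrom, 0, genome.length(chrom)))
        pos = np.array([s.pos - 1 for s in chrom_snps])
        refs = np.array([base_idx[s.ref.upper()] for s in chrom_snps])
        alts = np.array([base_idx[s.alt.upper()] for s in chrom_snps])
        for pwm in pwms:
            model = null_models[pwm.id]
            s_ref = batch_max_scores(codes, pos, refs, pwm)
            s_alt = batch_max_scores(codes, pos, alts, pwm)
            ok = np.isfinite(s_ref) & np.isfinite(s_alt)
            d = s_ref - s_alt
            p_diff = np.exp(-np.abs(d) / model.scale)
            p_ref = model.score_dist.sf_many(s_ref)
            p_alt = model.score_dist.sf_many(s_alt)
            hit = ok & (np.minimum(p_ref, p_alt) <= p_bind_max) \
                & (p_diff <= p_diff_max)
            for i in np.flatnonzero(hit):
                snp = chrom_snps[i]
                _, off, strand = max_binding_score(genome, chrom, snp.pos,
                                                   snp.ref, pwm)
                results.append(DiffBindResult(
                    snp_id=snp.rsid, motif_id=pwm.id,
                    score_ref=float(s_ref[i]), score_alt=float(s_alt[i]),
                    D=float(d[i]), p_bind_ref=float(p_ref[i]),
                    p_bind_alt=float(p_alt[i]), best_offset=off,
                    best_strand=strand, p_diff=float(p_diff[i])))
    results.sort(key=lambda r: (r.snp_id, r.p_diff, r.motif_id))
    return results


def results_to_frame(results: Sequence[DiffBindResult]) -> pd.DataFrame:
    """Tabulate scan results, one row per emitted SNP x motif pair."""
    cols = ["snp_id", "motif_id", "score_ref", "score_alt", "D",
            "p_bind_ref", "p_bind_alt", "p_diff", "best_offset", "best_strand"]
    if not results:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results])
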