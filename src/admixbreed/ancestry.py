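"""PCA-based local-ancestry deconvolution of phased haplotypes.

Haplotypes are cut into non-overlapping blocks of B consecutive SNPs
(default 10). Per block, a PCA over the pooled parental haplotype vectors
gives a one-dimensional score on which the two parental classes are modelled
as Gaussians; a query haplotype's block score then yields a posterior
probability of wolf vs dog origin, optionally smoothed along the chromosome
by a two-state HMM whose switch probability reflects an expected number of
generations since admixture. Hard calls require the posterior to clear a
threshold (default 0.8), else the block is uncalled.

Also provides the block-based genome-wide ancestry proportion q, a
supervised maximum-likelihood q from allele frequencies (the two-parental
stand-in for an unsupervised clustering run), ancestry-switch counting, and
detection of blocks fixed for one ancestry across a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import GeneticMap, GenotypeMatrix, HaplotypeSet
from .sim import DOG, WOLF


@dataclass
class BlockModel:
    chrom: str
    first: int            # first site index (global)
    last: int             # last site index (inclusive)
    start_bp: int
    end_bp: int
    center: np.ndarray    # per-site mean over pooled parental haplotypes
    axis: np.ndarray      # top principal axis
    mu_wolf: float
    mu_dog: float
    sigma: float
    informative: bool


@dataclass
class ReferencePanel:
    blocks: list
    block_size: int
    sites: pd.DataFrame

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass
class AncestryTrack:
    """Per-haplotype block posteriors and hard calls for one cohort."""

    hap_ids: list
    blocks: pd.DataFrame          # chrom, first, last, start_bp, end_bp, informative
    posterior_wolf: np.ndarray    # (n_haps, n_blocks)
    calls: np.ndarray             # (n_haps, n_blocks) of {WOLF, DOG, None}

    def sample_ids(self) -> list:
        return [h[:-3] for h in self.hap_ids[0::2]]


def build_reference(panel: HaplotypeSet, panel_groups, block_size: int = 10,
                    min_separation: float = 0.5) -> ReferencePanel:
    """Fit per-block PCA class models from labelled parental haplotypes.

    ``panel_groups`` maps each panel sample to ``wild_parent`` or
    ``dom_parent``. Blocks where the parental score distributions are
    separated by less than ``min_separation`` pooled SDs are flagged
    uninformative. Trailing partial blocks (< block_size sites) are dropped.
    """
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    groups = np.repeat([panel_groups[s] for s in panel.sample_ids], 2)
    is_wolf = groups == "wild_parent"
    is_dog = groups == "dom_parent"
    if not is_wolf.any() or not is_dog.any():
        raise ValueError("panel must contain both parental groups")
    chroms = panel.sites["chrom"].to_numpy()
    pos = panel.sites["pos"].to_numpy()
    blocks = []
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for lo in range(0, len(idx) - block_size + 1, block_size):
            sel = idx[lo:lo + block_size]
            h = panel.haplotypes[:, sel].astype(float)
            center = h.mean(axis=0)
            x = h - center
            # top principal axis of the pooled parental block
            _u, s, vt = np.linalg.svd(x, full_matrices=False)
            axis = vt[0]
            scores = x @ axis
            mu_w = scores[is_wolf].mean()
            mu_d = scores[is_dog].mean()
            sd = np.sqrt(0.5 * (scores[is_wolf].var() + scores[is_dog].var()))
            sd = max(sd, 1e-3)
            informative = s[0] > 1e-9 and abs(mu_w - mu_d) >= min_separation * sd
            blocks.append(BlockModel(
                chrom=chrom, first=int(sel[0]), last=int(sel[-1]),
                start_bp=int(pos[sel[0]]), end_bp=int(pos[sel[-1]]),
                center=center, axis=axis, mu_wolf=mu_w, mu_dog=mu_d,
                sigma=sd, informative=informative))
    return ReferencePanel(blocks=blocks, block_size=block_size,
                          sites=panel.sites.reset_index(drop=True))


def _hmm_smooth(p_wolf_obs, trans):
    """Two-state forward-backward with per-step switch probabilities."""
    n = len(p_wolf_obs)
    like = np.stack([p_wolf_obs, 1.0 - p_wolf_obs])  # state 0 = wolf
    fwd = np.zeros((2, n))
    bwd = np.ones((2, n))
    fwd[:, 0] = 0.5 * like[:, 0]
    fwd[:, 0] /= fwd[:, 0].sum()
    for t in range(1, n):
        s = trans[t - 1]
        m = np.array([[1 - s, s], [s, 1 - s]])
        fwd[:, t] = like[:, t] * (m.T @ fwd[:, t - 1])
        tot = fwd[:, t].sum()
        if tot > 0:
            fwd[:, t] /= tot
    for t in range(n - 2, -1, -1):
        s = trans[t]
        m = np.array([[1 - s, s], [s, 1 - s]])
        bwd[:, t] = m @ (like[:, t + 1] * bwd[:, t + 1])
        tot = bwd[:, t].sum()
        if tot > 0:
            bwd[:, t] /= tot
    post = fwd * bwd
    tot = post.sum(axis=0)
    tot[tot == 0] = 1.0
    return post[0] / tot


def deconvolve(hap: HaplotypeSet, ref: ReferencePanel, smooth: bool = True,
               hmm_generations: float = 10.0, call_threshold: float = 0.8,
               gmap: GeneticMap | None = None) -> AncestryTrack:
    """Assign per-block parental-origin posteriors to query haplotypes.

    Per block, Gaussian class likelihoods on the PCA score give
    P(wolf | score); with ``smooth`` a two-state HMM runs along each
    chromosome with switch probability 1 - exp(-g * d) for block genetic
    distance d (Morgans) and prior g = ``hmm_generations``. Uninformative
    blocks contribute flat likelihoods and stay uncalled unless the HMM
    resolves them.
    """
    if not hap.sites[["chrom", "pos"]].equals(ref.sites[["chrom", "pos"]]):
        raise ValueError("query sites do not match the reference panel")
    if gmap is None:
        gmap = GeneticMap()
    n_haps = 2 * hap.n_samples
    n_blocks = ref.n_blocks
    p_obs = np.full((n_haps, n_blocks), 0.5)
    for k, bl in enumerate(ref.blocks):
        if not bl.informative:
            continue
        h = hap.haplotypes[:, bl.first:bl.last + 1].astype(float)
        scores = (h - bl.center) @ bl.axis
        lw = np.exp(-0.5 * ((scores - bl.mu_wolf) / bl.sigma) ** 2)
        ld = np.exp(-0.5 * ((scores - bl.mu_dog) / bl.sigma) ** 2)
        tot = lw + ld
        ok = tot > 0
        p_obs[ok, k] = lw[ok] / tot[ok]
        p_obs[~ok, k] = 0.5

    post = p_obs.copy()
    block_chrom = np.array([bl.chrom for bl in ref.blocks], dtype=object)
    if smooth and n_blocks:
        mids = np.array([0.5 * (bl.start_bp + bl.end_bp) for bl in ref.blocks])
        for chrom in dict.fromkeys(block_chrom):
            sel = np.flatnonzero(block_chrom == chrom)
            if len(sel) < 2:
                continue
            d = np.diff([gmap.bp_to_morgans(chrom, m) for m in mids[sel]])
            trans = np.clip(1.0 - np.exp(-hmm_generations * d), 1e-6, 0.5)
            for r in range(n_haps):
                post[r, sel] = _hmm_smooth(p_obs[r, sel], trans)

    calls = np.full((n_haps, n_blocks), None, dtype=object)
    calls[post > call_threshold] = WOLF
    calls[post < 1.0 - call_threshold] = DOG

    blocks_df = pd.DataFrame({
        "chrom": block_chrom,
        "first": [bl.first for bl in ref.blocks],
        "last": [bl.last for bl in ref.blocks],
        "start_bp": [bl.start_bp for bl in ref.blocks],
        "end_bp": [bl.end_bp for bl in ref.blocks],
        "informative": [bl.informative for bl in ref.blocks],
    })
    return AncestryTrack(hap_ids=hap.hap_ids(), blocks=blocks_df,
                         posterior_wolf=post, calls=calls)


def genome_wide_ancestry(track: AncestryTrack) -> pd.DataFrame:
    """Per-individual wolf fraction q from called blocks.

    ``q`` is the fraction of called blocks assigned wolf, pooled over the two
    haplotypes; ``q_weighted`` weights blocks by bp span. Individuals with no
    called block get NaN and are flagged.
    """
    spans = (track.blocks["end_bp"] - track.blocks["start_bp"]).to_numpy().astype(float)
    rows = []
    for i, sid in enumerate(track.sample_ids()):
        calls = np.concatenate([track.calls[2 * i], track.calls[2 * i + 1]])
        w = np.concatenate([spans, spans])
        called = calls != None  # noqa: E711  (object array)
        if called.sum() == 0:
            rows.append({"sample": sid, "q": np.nan, "q_weighted": np.nan,
                         "n_called": 0, "flagged": True})
            continue
        is_wolf = calls == WOLF
        q = is_wolf[called].mean()
        qw = w[called & is_wolf].sum() / w[called].sum()
        rows.append({"sample": sid, "q": float(q), "q_weighted": float(qw),
                     "n_called": int(called.sum()), "flagged": False})
    return pd.DataFrame(rows).set_index("sample")


def supervised_q(gm: GenotypeMatrix, p_wolf: np.ndarray, p_dog: np.ndarray,
                 samples=None, tol: float = 1e-6) -> pd.Series:
    """Maximum-likelihood ancestry proportion q per individual.

    Maximizes the binomial log-likelihood of each dosage given the mixed
    allele frequency q * p_wolf + (1 - q) * p_dog over q in [0, 1].
    Frequencies are clipped away from 0/1 by 1/(2n+1) before use.
    """
    if samples is None:
        samples = [s for s, g in zip(gm.sample_ids, gm.groups) if g == "breed"]
    n_ref = max(len(p_wolf), 1)
    eps = 1.0 / (2 * n_ref + 1)
    pw = np.clip(p_wolf, eps, 1 - eps)
    pd_ = np.clip(p_dog, eps, 1 - eps)
    informative = np.abs(pw - pd_) > 1e-12
    out = {}
    for sid in samples:
        i = gm.sample_ids.index(sid)
        calls = gm.calls[i]
        ok = (calls >= 0) & informative
        if ok.sum() == 0:
            raise ValueError(f"no informative sites for sample {sid}")
        d = calls[ok].astype(float)
        a, b = pw[ok], pd_[ok]

        def nll(q):
            p = q * a + (1 - q) * b
            return -(d * np.log(p) + (2 - d) * np.log(1 - p)).sum()

        res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": tol})
        out[sid] = float(res.x)
    return pd.Series(out, name="q_supervised")


def count_switches(track: AncestryTrack) -> pd.Series:
    """Ancestry junctions per individual: adjacent called blocks that differ.

    Uncalled blocks are skipped (the flanking called blocks are compared);
    counts sum over both haplotypes and all chromosomes.
    """
    block_chrom = track.blocks["chrom"].to_numpy()
    out = {}
    for i, sid in enumerate(track.sample_ids()):
        s = 0
        for r in (2 * i, 2 * i + 1):
            for chrom in dict.fromkeys(block_chrom):
                sel = np.flatnonzero(block_chrom == chrom)
                calls = [c for c in track.calls[r, sel] if c is not None]
                s += sum(1 for a, b in zip(calls, calls[1:]) if a != b)
        out[sid] = s
    return pd.Series(out, name="switches")


def fixed_ancestry_blocks(track: AncestryTrack, samples=None):
    """Blocks where every haplotype of every individual carries one ancestry.

    Returns (wolf_fixed, dog_fixed) boolean arrays over blocks; a block with
    any uncalled haplotype is excluded from both.
    """
    if samples is None:
        rows = np.arange(track.posterior_wolf.shape[0])
    else:
        sids = track.sample_ids()
        rows = np.concatenate([[2 * sids.index(s), 2 * sids.index(s) + 1]
                               for s in samples])
    calls = track.calls[rows]
    all_called = (calls != None).all(axis=0)  # noqa: E711
    wolf_fixed = all_called & (calls == WOLF).all(axis=0)
    dog_fixed = all_called & (calls == DOG).all(axis=0)
    return wolf_fixed, dog_fixed


__all__ = [
    "BlockModel", "ReferencePanel", "AncestryTrack", "build_reference",
    "deconvolve", "genome_wide_ancestry", "supervised_q", "count_switches",
    "fixed_ancestry_blocks",
]
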