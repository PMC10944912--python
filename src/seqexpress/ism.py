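"""In-silico saturation mutagenesis (ISM) and variant effect prediction.

Every position of a gene's promoter window is substituted to each of the
three alternative bases and re-scored with the trained ensemble; the effect
of a substitution is (mutant prediction - wild-type prediction) on the
unstandardized log10 expression scale, so a positive effect means the
mutation is predicted to increase expression. Half-life features are held
fixed across mutations. Per-position summaries keep, for each position, the
substitution with the largest absolute effect; averaging that quantity over
a gene set (e.g., 2,000 highly variable genes) gives the positional
importance profile of the window. Single variants are scored the same way
and ranked against the gene's full ISM effect distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import SequenceWindow
from .encoding import CHANNELS, one_hot
from .model import ModelEnsemble, predict

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class OutOfWindowError(ValueError):
    """Variant position falls outside the gene's sequence window."""


class AlleleMismatchError(ValueError):
    """Stated reference allele disagrees with the genome sequence."""


@dataclass
class ISMProfile:
    """Full saturation-mutagenesis result for one gene.

    ``effects[i, j, t]`` is the predicted expression change in task ``t``
    when position ``i`` is substituted to ``alts[i][j]`` (the three non-
    reference bases in A<C<G<T order). Positions with an ambiguous
    reference base carry NaN effects and empty ``alts``.
    """

    gene_id: str
    ref_seq: str
    effects: np.ndarray  # (L, 3, n_tasks), unstandardized log10 scale
    alts: list[tuple[str, ...]]
    task_names: list[str]
    wildtype_prediction: np.ndarray  # (n_tasks,), unstandardized

    @property
    def length(self) -> int:
        return self.effects.shape[0]

    def task_index(self, task: str) -> int:
        return self.task_names.index(task)


def saturation_mutagenesis(
    ensemble: ModelEnsemble,
    window: SequenceWindow,
    halflife: np.ndarray,
    chunk_size: int = 512,
) -> ISMProfile:
    """Score all 3L single-base substitutions of a window with the ensemble.

    ``halflife`` is the gene's normalized 5-vector, held fixed for every
    mutant. Mutants are evaluated in chunks to bound memory.
    """
    seq = window.seq.upper()
    length = len(seq)
    n_tasks = ensemble.config.n_tasks
    wt_mat = one_hot(seq, window.gene_id).values
    hl = np.asarray(halflife, dtype=np.float32).reshape(1, -1)
    wt_pred = predict(ensemble, wt_mat[None], hl, unstandardized=True)[0]

    jobs: list[tuple[int, int, int]] = []  # (position, slot, alt channel)
    alts: list[tuple[str, ...]] = []
    for i, ref in enumerate(seq):
        if ref in _COMP:
            alt_bases = tuple(b for b in CHANNELS if b != ref)
            alts.append(alt_bases)
            for j, alt in enumerate(alt_bases):
                jobs.append((i, j, CHANNELS.index(alt)))
        else:
            alts.append(())  # ambiguous reference: effects stay missing

    effects = np.full((length, 3, n_tasks), np.nan)
    for start in range(0, len(jobs), chunk_size):
        batch = jobs[start : start + chunk_size]
        x = np.repeat(wt_mat[None], len(batch), axis=0)
        for r, (i, _, ci) in enumerate(batch):
            x[r, :, i] = 0.0
            x[r, ci, i] = 1.0
        preds = predict(
            ensemble, x, np.repeat(hl, len(batch), axis=0), unstandardized=True
        )
        for r, (i, j, _) in enumerate(batch):
            effects[i, j] = preds[r] - wt_pred
    return ISMProfile(
        gene_id=window.gene_id,
        ref_seq=seq,
        effects=effects,
        alts=alts,
        task_names=list(ensemble.task_names),
        wildtype_prediction=wt_pred,
    )


def max_effect_profile(profile: ISMProfile, task: str) -> np.ndarray:
    """Per-position signed effect of the largest-|effect| substitution.

    Ties are broken by the fixed A<C<G<T alternative order; ambiguous
    positions are NaN.
    """
    t = profile.task_index(task)
    eff = profile.effects[:, :, t]  # (L, 3)
    out = np.full(profile.length, np.nan)
    valid = ~np.isnan(eff).all(axis=1)
    absval = np.where(np.isnan(eff), -np.inf, np.abs(eff))
    idx = absval.argmax(axis=1)  # argmax takes the first maximum: A<C<G<T order
    out[valid] = eff[np.arange(profile.length), idx][valid]
    return out


def hvg_mean_max_profile(profiles: list[ISMProfile], task: str) -> np.ndarray:
    """Mean over genes of the per-position maximum absolute effect.

    ymax(i) = (1/|G|) * sum_g max_alt |effect_g(i, alt)|. Ambiguous
    positions are excluded gene-wise via NaN-aware averaging.
    """
    lengths = {p.length for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"profiles have mixed window lengths: {sorted(lengths)}")
    rows = []
    for p in profiles:
        t = p.task_index(task)
        with np.errstate(invalid="ignore"):
            rows.append(np.nanmax(np.abs(p.effects[:, :, t]), axis=1))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(np.stack(rows), axis=0)


def sign_consistent_difference(
    profile: ISMProfile, task_a: str, task_b: str
) -> np.ndarray:
    """Difference of two tasks' max-effect profiles, NaN where they disagree
    in sign (those positions are reported separately rather than differenced)."""
    a = max_effect_profile(profile, task_a)
    b = max_effect_profile(profile, task_b)
    diff = a - b
    diff[np.sign(a) * np.sign(b) < 0] = np.nan
    return diff


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based genomic position (VCF convention)
    ref: str  # forward-strand allele
    alt: str | None  # forward-strand allele; None = score all three
    gene_id: str
    variant_id: str = ""


@dataclass
class VariantEffect:
    """Predicted per-task effect of one substitution, window-oriented."""

    variant_id: str
    gene_id: str
    offset: int  # position within the window (0-based; up_len = TSS)
    ref: str  # window-oriented alleles
    alt: str
    effects: np.ndarray  # (n_tasks,), unstandardized log10 scale
    task_names: list[str]
    percentile: np.ndarray | None = None  # rank of |effect| in the gene's ISM


def window_offset(window: SequenceWindow, pos: int) -> int:
    """Map a 1-based genomic position into the oriented window coordinate."""
    pos0 = pos - 1
    if window.strand == "+":
        offset = pos0 - (window.tss - window.up_len)
    else:
        offset = (window.tss + window.up_len) - pos0
    if not 0 <= offset < window.up_len + window.down_len:
        raise OutOfWindowError(
            f"position {pos} ({window.chrom}) is outside the window of "
            f"{window.gene_id} (TSS {window.tss + 1}, -{window.up_len}/+{window.down_len})"
        )
    return offset


def variant_effect(
    ensemble: ModelEnsemble,
    window: SequenceWindow,
    halflife: np.ndarray,
    variant: VariantRecord,
    profile: ISMProfile | None = None,
) -> list[VariantEffect]:
    """Score a variant against one gene's window.

    The stated reference allele must match the genome (alleles are given on
    the forward strand and complemented internally for minus-strand genes).
    Returns one record per alternative (all three when ``variant.alt`` is
    None). If a precomputed ``profile`` is given, effects are read from it
    and percentile ranks against the full ISM distribution are attached;
    otherwise only the requested substitutions are evaluated.
    """
    offset = window_offset(window, variant.pos)
    ref_w = variant.ref.upper()
    alt_w = variant.alt.upper() if variant.alt else None
    if window.strand == "-":
        ref_w = _COMP.get(ref_w, ref_w)
        alt_w = _COMP.get(alt_w, alt_w) if alt_w else None
    genome_base = window.seq[offset].upper()
    if genome_base != ref_w:
        raise AlleleMismatchError(
            f"variant {variant.variant_id or variant.pos}: stated reference "
            f"{ref_w!r} but genome has {genome_base!r} at window offset {offset} "
            f"of {window.gene_id}"
        )
    alt_bases = [alt_w] if alt_w else [b for b in CHANNELS if b != ref_w]

    if profile is None:
        profile_local = None
        seq = window.seq.upper()
        hl = np.asarray(halflife, dtype=np.float32).reshape(1, -1)
        wt_mat = one_hot(seq).values
        wt_pred = predict(ensemble, wt_mat[None], hl, unstandardized=True)[0]
        effects_by_alt = {}
        for alt in alt_bases:
            x = wt_mat[None].copy()
            x[0, :, offset] = 0.0
            x[0, CHANNELS.index(alt), offset] = 1.0
            effects_by_alt[alt] = predict(ensemble, x, hl, unstandardized=True)[0] - wt_pred
    else:
        profile_local = profile
        if profile.ref_seq[offset] != ref_w:
            raise AlleleMismatchError(
                f"profile reference {profile.ref_seq[offset]!r} does not match "
                f"variant reference {ref_w!r}"
            )
        effects_by_alt = {
            alt: profile.effects[offset, profile.alts[offset].index(alt)]
            for alt in alt_bases
        }

    results = []
    for alt in alt_bases:
        eff = np.asarray(effects_by_alt[alt], dtype=np.float64)
        pct = None
        if profile_local is not None:
            flat = np.abs(profile_local.effects)  # (L, 3, T)
            pct = np.array(
                [
                    stats.percentileofscore(
                        flat[:, :, t][~np.isnan(flat[:, :, t])].ravel(),
                        abs(eff[t]),
                        kind="weak",
                    )
                    for t in range(len(ensemble.task_names))
                ]
            )
        results.append(
            VariantEffect(
                variant_id=variant.variant_id,
                gene_id=window.gene_id,
                offset=offset,
                ref=ref_w,
                alt=alt,
                effects=eff,
                task_names=list(ensemble.task_names),
                percentile=pct,
            )
        )
    return results


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read a variant table: TSV (chrom pos id ref alt gene) or minimal VCF
    with a ``gene`` tag in the INFO column."""
    records = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if any(l.startswith("##fileformat=VCF") for l in lines):
        for line in lines:
            if line.startswith("#"):
                continue
            f = line.split("\t")
            info = dict(
                kv.split("=", 1) for kv in f[7].split(";") if "=" in kv
            ) if len(f) > 7 else {}
            records.append(
                VariantRecord(
                    chrom=f[0], pos=int(f[1]), variant_id=f[2],
                    ref=f[3], alt=None if f[4] == "." else f[4],
                    gene_id=info.get("gene", ""),
                )
            )
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = {c.lower(): c for c in df.columns}
        for _, row in df.iterrows():
            alt = row[cols["alt"]] if "alt" in cols else None
            if isinstance(alt, str) and alt in (".", ""):
                alt = None
            records.append(
                VariantRecord(
                    chrom=str(row[cols["chrom"]]),
                    pos=int(row[cols["pos"]]),
                    ref=str(row[cols["ref"]]),
                    alt=alt,
                    gene_id=str(row[cols["gene"]]),
                    variant_id=str(row[cols["id"]]) if "id" in cols else "",
                )
            )
    return records


def profile_to_frame(profile: ISMProfile) -> pd.DataFrame:
    """Long-format table (position, ref, alt, effect per task) for export."""
    rows = []
    for i in range(profile.length):
        for j, alt in enumerate(profile.alts[i]):
            row = {"position": i, "ref": profile.ref_seq[i], "alt": alt}
            for t, name in enumerate(profile.task_names):
                row[f"effect_{name}"] = profile.effects[i, j, t]
            rows.append(row)
    return pd.DataFrame(rows)


def write_max_effect_bedgraph(
    profile: ISMProfile, window: SequenceWindow, task: str, path: str | Path
) -> None:
    """Per-position max-|effect| as a bedGraph-style track in genomic coords."""
    vals = np.abs(max_effect_profile(profile, task))
    with open(path, "w") as fh:
        for i, v in enumerate(vals):
            if np.isnan(v):
                continue
            if window.strand == "+":
                g = window.tss - window.up_len + i
            else:
                g = window.tss + window.up_len - i
            fh.write(f"{window.chrom}\t{g}\t{g + 1}\t{v:.6g}\n")
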