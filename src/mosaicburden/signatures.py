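"""Trinucleotide mutational-signature extraction and refitting.

Single-base substitutions are binned into the standard 96-channel catalog:
6 pyrimidine-centred substitution classes (C>A, C>G, C>T, T>A, T>C, T>G)
by 16 flanking-base pairs; purine-reference substitutions are mapped by
reverse complement. Observed spectra are decomposed onto a signature
catalog (e.g. COSMIC SBS) by non-negative least squares, giving per-
signature exposures and relative fractions; condition-level fractions are
compared with seeded bootstrap confidence intervals over SNVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from ._rng import child_rng

__all__ = [
    "CHANNELS",
    "channel_of",
    "context_spectrum",
    "SignatureCatalog",
    "synthetic_catalog",
    "SignatureExposure",
    "fit_signatures",
    "compare_condition_fractions",
]

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
FLANKS = ("A", "C", "G", "T")

#: Canonical 96-channel order: substitution-major, then 5' and 3' flank.
CHANNELS = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in FLANKS for f3 in FLANKS
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


def channel_of(ref: str, alt: str, flank5: str, flank3: str) -> str:
    """Map one stranded substitution-with-flanks to its pyrimidine channel.

    Purine-reference events (ref A or G) are reverse-complemented: the
    substitution is complemented and the flanks swap roles. The mapping is a
    2-to-1 surjection from the 192 stranded contexts onto the 96 channels.
    """
    if ref == alt:
        raise ValueError("ref and alt must differ")
    for b in (ref, alt, flank5, flank3):
        if b not in COMPLEMENT:
            raise ValueError(f"invalid base {b!r}")
    if ref in ("A", "G"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        flank5, flank3 = COMPLEMENT[flank3], COMPLEMENT[flank5]
    return f"{flank5}[{ref}>{alt}]{flank3}"


def context_spectrum(
    snvs: pd.DataFrame, reference: dict[str, str]
) -> tuple[np.ndarray, int]:
    """Count SNVs into the 96-channel spectrum.

    ``snvs`` needs columns ``chrom, pos, ref, alt`` (0-based positions).
    SNVs at a contig edge (no flanking base on either side) are skipped and
    counted; the spectrum sum equals the number of non-skipped SNVs.
    Returns ``(spectrum, n_skipped)``.
    """
    spectrum = np.zeros(96, dtype=float)
    n_skipped = 0
    for row in snvs.itertuples():
        seq = reference.get(row.chrom)
        if seq is None:
            raise ValueError(f"contig {row.chrom!r} absent from reference")
        pos = int(row.pos)
        if pos - 1 < 0 or pos + 1 >= len(seq):
            n_skipped += 1
            continue
        if seq[pos] != row.ref:
            raise ValueError(
                f"reference mismatch at {row.chrom}:{pos}: "
                f"pileup says {row.ref!r}, sequence says {seq[pos]!r}"
            )
        ch = channel_of(row.ref, row.alt, seq[pos - 1], seq[pos + 1])
        spectrum[_CHANNEL_INDEX[ch]] += 1
    return spectrum, n_skipped


@dataclass
class SignatureCatalog:
    """K signatures x 96 channel probabilities (rows sum to 1)."""

    matrix: np.ndarray  # shape (K, 96)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 96:
            raise ValueError("catalog matrix must be K x 96")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("label count must match signature count")
        if np.any(self.matrix < 0):
            raise ValueError("catalog entries must be non-negative")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("each signature must sum to 1 within 1e-6")

    @classmethod
    def from_cosmic_tsv(cls, path) -> "SignatureCatalog":
        """Read a COSMIC-layout signature TSV (Type column + one column per
        signature), reordering channels into the canonical order and
        renormalizing rows to absorb file rounding."""
        df = pd.read_csv(path, sep="\t")
        type_col = df.columns[0]
        df = df.set_index(type_col)
        missing = set(CHANNELS) - set(df.index)
        if missing:
            raise ValueError(f"catalog file missing channel(s): {sorted(missing)[:5]}")
        df = df.loc[list(CHANNELS)]
        mat = df.to_numpy(dtype=float).T
        mat = mat / mat.sum(axis=1, keepdims=True)
        return cls(matrix=mat, labels=tuple(df.columns))

    def to_cosmic_tsv(self, path) -> None:
        pd.DataFrame(
            self.matrix.T, index=pd.Index(CHANNELS, name="Type"), columns=self.labels
        ).to_csv(path, sep="\t")


def synthetic_catalog(n_signatures: int = 5, seed: int = 7) -> SignatureCatalog:
    """A small synthetic signature catalog (not COSMIC data).

    Dirichlet-drawn sparse profiles; the first label is "SBS26" so that
    pipelines exercising DNA-damage-signature comparisons have a named
    mismatch-repair-style signature to track. Purely synthetic stand-in for
    a real catalog, which users supply via :meth:`SignatureCatalog.from_cosmic_tsv`.
    """
    rng = child_rng(seed, "signature_catalog")
    mat = rng.dirichlet(np.full(96, 0.15), size=n_signatures)
    labels = ["SBS26"] + [f"SYN{i}" for i in range(1, n_signatures)]
    return SignatureCatalog(matrix=mat, labels=tuple(labels[:n_signatures]))


@dataclass
class SignatureExposure:
    """NNLS decomposition of one spectrum onto a catalog."""

    weights: pd.Series
    residual: float
    total: float
    degenerate: bool = False  # zero input spectrum

    @property
    def fractions(self) -> pd.Series:
        """Relative signature fractions; NaN when the spectrum was empty."""
        s = float(self.weights.sum())
        if s <= 0:
            return pd.Series(np.nan, index=self.weights.index)
        return self.weights / s


def fit_signatures(spectrum: np.ndarray, catalog: SignatureCatalog) -> SignatureExposure:
    """Non-negative least-squares refit of a 96-channel spectrum.

    Minimizes ``|| spectrum - w @ catalog ||_2`` subject to ``w >= 0``
    (deterministic active-set solver). Fractions are scale-invariant in the
    spectrum; a zero spectrum yields zero weights flagged degenerate.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (96,):
        raise ValueError("spectrum must have 96 channels")
    if np.any(spectrum < 0):
        raise ValueError("spectrum counts must be non-negative")
    total = float(spectrum.sum())
    if total == 0:
        return SignatureExposure(
            weights=pd.Series(0.0, index=list(catalog.labels)),
            residual=0.0, total=0.0, degenerate=True,
        )
    w, rnorm = optimize.nnls(catalog.matrix.T, spectrum)
    return SignatureExposure(
        weights=pd.Series(w, index=list(catalog.labels)),
        residual=float(rnorm), total=total,
    )


def compare_condition_fractions(
    snvs_by_condition: dict[str, pd.DataFrame],
    reference: dict[str, str],
    catalog: SignatureCatalog,
    n_boot: int = 1000,
    seed: int = 0,
    low_confidence_below: int = 50,
) -> pd.DataFrame:
    """Side-by-side signature fractions per condition with bootstrap CIs.

    For each condition the observed spectrum is refitted; 95% CIs come from
    ``n_boot`` seeded bootstrap resamples of that condition's SNVs.
    Conditions with fewer than ``low_confidence_below`` SNVs are flagged.
    """
    if len(snvs_by_condition) < 2:
        raise ValueError("need at least 2 conditions to compare")
    rows = []
    for cond, snvs in sorted(snvs_by_condition.items()):
        spectrum, _ = context_spectrum(snvs, reference)
        exp = fit_signatures(spectrum, catalog)
        rng = child_rng(seed, f"boot:{cond}")
        boot = np.full((n_boot, len(catalog.labels)), np.nan)
        n = len(snvs)
        for b in range(n_boot if n else 0):
            take = rng.integers(0, n, size=n)
            bs, _ = context_spectrum(snvs.iloc[take], reference)
            boot[b] = fit_signatures(bs, catalog).fractions.to_numpy()
        lo = np.nanpercentile(boot, 2.5, axis=0)
        hi = np.nanpercentile(boot, 97.5, axis=0)
        for j, sig in enumerate(catalog.labels):
            rows.append(
                {
                    "condition": cond,
                    "signature": sig,
                    "fraction": float(exp.fractions.iloc[j]),
                    "ci_low": float(lo[j]),
                    "ci_high": float(hi[j]),
                    "n_snvs": n,
                    "low_confidence": n < low_confidence_below,
                }
            )
    return pd.DataFrame(rows)


def plot_condition_fractions(fracs: pd.DataFrame, ax=None):
    """Grouped bar chart of signature fractions by condition with CIs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    conds = sorted(fracs.condition.unique())
    sigs = list(fracs.signature.unique())
    width = 0.8 / len(conds)
    x = np.arange(len(sigs))
    for k, cond in enumerate(conds):
        sub = fracs[fracs.condition == cond].set_index("signature").loc[sigs]
        err = np.vstack(
            [sub.fraction - sub.ci_low, sub.ci_high - sub.fraction]
        ).clip(min=0)
        ax.bar(x + k * width, sub.fraction, width, yerr=err, capsize=2, label=cond)
    ax.set_xticks(x + width * (len(conds) - 1) / 2)
    ax.set_xticklabels(sigs, rotation=45, ha="right")
    ax.set_ylabel("signature fraction")
    ax.legend()
    return ax
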