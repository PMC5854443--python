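"""Sequence-derived scores and the gene-level feature table.

Covers three sequence primitives and their roll-up into per-gene features:

* ESR hexamer scoring: the wild-type-minus-mutant difference in summed
  exonic-splicing-regulatory hexamer scores over the six sliding windows
  that overlap a substitution;
* splice-site position weight matrices (PWMs): per-position log-odds models
  of donor (9 positions, -3..+6) and acceptor (23 positions, -20..+3) sites,
  and the delta score (reference minus alternate) of a splice-region
  variant — positive delta weakens the site;
* the 19-feature gene table feeding the SSM-prone classifiers (intron
  count, exon length/structure, haploinsufficiency, motif densities,
  splice-site strengths, SNP densities, conservation, lengths).

RNA secondary-structure free energy enters only through a pluggable
``fold_backend`` callable (sequence -> kcal/mol-like scalar); the default is
a simple GC-weighted stacking heuristic and tests inject fixed scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel

log = logging.getLogger("ssmprone")

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SITE_LENGTHS = {"5ss": 9, "3ss": 23}       # -3..+6 and -20..+3
SITE_OFFSETS = {
    "5ss": tuple(o for o in range(-3, 7) if o != 0),
    "3ss": tuple(o for o in range(-20, 4) if o != 0),
}


def _norm_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# ESR hexamers
# ---------------------------------------------------------------------------

@dataclass
class HexamerTable:
    """Scores (and optional ESE/ESS/ESR class) for 6-mers."""

    scores: dict[str, float]
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {}
        for hexamer, score in self.scores.items():
            h = _norm_seq(hexamer)
            if len(h) != 6 or any(b not in BASE_INDEX for b in h):
                raise ValueError(f"invalid hexamer {hexamer!r}")
            if h in norm:
                raise ValueError(f"duplicate hexamer {hexamer!r}")
            norm[h] = float(score)
        self.scores = norm
        self.classes = {_norm_seq(k): v for k, v in self.classes.items()}

    def score(self, hexamer: str) -> float:
        return self.scores.get(_norm_seq(hexamer), 0.0)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HexamerTable":
        df = pd.read_csv(path, sep="\t")
        if "hexamer" not in df.columns or "score" not in df.columns:
            raise ValueError("hexamer table needs columns 'hexamer' and 'score'")
        classes = (dict(zip(df["hexamer"], df["class"]))
                   if "class" in df.columns else {})
        return cls(scores=dict(zip(df["hexamer"], df["score"])), classes=classes)

    def to_tsv(self, path: str | Path) -> None:
        rows = [(h, s, self.classes.get(h, "")) for h, s in sorted(self.scores.items())]
        pd.DataFrame(rows, columns=["hexamer", "score", "class"]).to_csv(
            path, sep="\t", index=False)


def window_esr_score(seq: str, table: HexamerTable) -> float:
    """Summed hexamer score over every 6-mer window of a sequence."""
    seq = _norm_seq(seq)
    return float(sum(table.score(seq[p:p + 6]) for p in range(len(seq) - 5)))


def delta_esr(wt_seq: str, mt_seq: str, table: HexamerTable, variant_offset: int) -> float:
    """Wild-type minus mutant summed ESR score around a single substitution.

    Only the up-to-six hexamer windows overlapping ``variant_offset`` are
    scored (windows truncated at the sequence ends); step size is one
    nucleotide. Windows away from the variant are identical in both alleles
    and cancel, so this equals the full-sequence score difference.
    """
    wt, mt = _norm_seq(wt_seq), _norm_seq(mt_seq)
    if len(wt) != len(mt):
        raise ValueError("wild-type and mutant sequences must have equal length")
    diffs = [i for i, (a, b) in enumerate(zip(wt, mt)) if a != b]
    if len(diffs) != 1:
        raise ValueError("delta_esr supports exactly one substitution (no indels)")
    if diffs[0] != variant_offset:
        raise ValueError(f"substitution at {diffs[0]}, not at variant_offset={variant_offset}")
    lo = max(0, variant_offset - 5)
    hi = min(len(wt) - 6, variant_offset)
    total = 0.0
    for p in range(lo, hi + 1):
        total += table.score(wt[p:p + 6]) - table.score(mt[p:p + 6])
    return total


def esr_density(seq: str, table: HexamerTable, hexamer_class: str | None = None) -> float:
    """Motif hits per exonic nucleotide (hexamer windows with nonzero score)."""
    seq = _norm_seq(seq)
    if len(seq) == 0:
        return 0.0
    hits = 0
    for p in range(len(seq) - 5):
        h = seq[p:p + 6]
        if h in table.scores and (
                hexamer_class is None or table.classes.get(h) == hexamer_class):
            hits += 1
    return hits / len(seq)


# ---------------------------------------------------------------------------
# Splice-site PWM
# ---------------------------------------------------------------------------

@dataclass
class SpliceSitePWM:
    """Per-position log2-odds model of a splice site.

    ``matrix`` is (length x 4) log2 odds over A, C, G, T relative to the
    background base frequencies; scores of a sequence sum over positions.
    """

    site_kind: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        expected = SITE_LENGTHS.get(self.site_kind)
        if expected is not None and self.matrix.shape != (expected, 4):
            raise ValueError(
                f"{self.site_kind} PWM must be ({expected}, 4), got {self.matrix.shape}")
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have 4 base columns")
        if not np.isfinite(self.matrix).all():
            raise ValueError("PWM log-odds must be finite (use a pseudocount)")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def score(self, seq: str) -> float:
        seq = _norm_seq(seq)
        if len(seq) != self.length:
            raise ValueError(f"sequence length {len(seq)} != PWM length {self.length}")
        return float(sum(self.matrix[i, BASE_INDEX[b]] for i, b in enumerate(seq)))

    @property
    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.matrix.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def delta(self, ref_site: str, alt_site: str) -> float:
        """Reference minus alternate score; positive = site weakening."""
        return self.score(ref_site) - self.score(alt_site)


def build_pwm(training_sites: Sequence[str], site_kind: str,
              pseudocount: float = 0.5,
              background: Sequence[float] | None = None,
              min_sites: int = 50) -> SpliceSitePWM:
    """Estimate a splice-site PWM from aligned training sites.

    Per position, log2( (count + pseudocount) / (N + 4*pseudocount) /
    background ). The consensus sequence attains the maximal possible score
    by construction. Sites of the wrong length are rejected with their index.
    """
    if len(training_sites) < min_sites:
        raise ValueError(f"need >= {min_sites} training sites, got {len(training_sites)}")
    length = SITE_LENGTHS.get(site_kind, len(_norm_seq(training_sites[0])))
    counts = np.zeros((length, 4))
    for idx, site in enumerate(training_sites):
        s = _norm_seq(site)
        if len(s) != length:
            raise ValueError(f"training site {idx} has length {len(s)}, expected {length}")
        for i, b in enumerate(s):
            if b not in BASE_INDEX:
                raise ValueError(f"training site {idx}: invalid base {b!r}")
            counts[i, BASE_INDEX[b]] += 1
    bg = np.asarray(background, dtype=float) if background is not None else np.full(4, 0.25)
    n = len(training_sites)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    return SpliceSitePWM(site_kind=site_kind, matrix=np.log2(probs / bg), background=bg)


def site_sequence(gene: GeneModel, kind: str, intron_index: int,
                  genome: Mapping[str, str]) -> str:
    """Splice-site window sequence in transcript orientation."""
    chrom_seq = genome[gene.chrom]
    bases = []
    for off in SITE_OFFSETS[kind]:
        pos = gene.site_position(kind, intron_index, off)
        b = chrom_seq[pos]
        bases.append(_complement(b) if gene.strand == "-" else b)
    return "".join(bases)


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _complement(b: str) -> str:
    return b.translate(_COMP)


def score_variant_delta(variant, pwm5: SpliceSitePWM, pwm3: SpliceSitePWM,
                        gene: GeneModel, genome: Mapping[str, str]) -> float:
    """PWM delta of a splice-region variant: score(ref site) - score(alt site).

    ``variant`` needs attributes position (0-based), ref and alt. Raises if
    the position is not inside any canonical splice-site window of the gene.
    Positive delta weakens the site; delta < 0 strengthens it.
    """
    for kind, pwm in (("5ss", pwm5), ("3ss", pwm3)):
        for i in range(gene.n_introns):
            off = gene.site_offset(kind, i, variant.position)
            lo, hi = SITE_OFFSETS[kind][0], SITE_OFFSETS[kind][-1]
            if not (lo <= off <= hi) or off == 0:
                continue
            ref_site = site_sequence(gene, kind, i, genome)
            idx = SITE_OFFSETS[kind].index(off)
            ref_b = variant.ref if gene.strand == "+" else _complement(variant.ref)
            alt_b = variant.alt if gene.strand == "+" else _complement(variant.alt)
            if ref_site[idx].upper() != ref_b.upper():
                raise ValueError(
                    f"reference mismatch at {variant.position}: genome has "
                    f"{ref_site[idx]!r}, variant says {variant.ref!r}")
            alt_site = ref_site[:idx] + alt_b + ref_site[idx + 1:]
            return pwm.delta(ref_site, alt_site)
    raise ValueError(f"position {variant.position} is not a splice-site variant "
                     f"of gene {gene.gene_id}")


# ---------------------------------------------------------------------------
# Folding backend
# ---------------------------------------------------------------------------

def stacking_fold_backend(seq: str) -> float:
    """Crude free-energy-like scalar from dinucleotide stacking weights.

    Each adjacent base pair step contributes a negative increment, larger in
    magnitude for GC-rich steps (-0.5 kcal/mol per G/C in the step, -0.1 per
    A/T), mimicking the first-order trend that GC-rich sequences fold more
    stably. Interchangeable with any callable sequence -> scalar.
    """
    seq = _norm_seq(seq)
    dg = 0.0
    for a, b in zip(seq, seq[1:]):
        dg -= sum(0.5 if x in "GC" else 0.1 for x in (a, b)) / 2.0
    return dg


def rnafold_backend(seq: str) -> float:
    """Minimum free energy from the RNAfold command-line tool, if installed."""
    import re
    import subprocess

    out = subprocess.run(["RNAfold", "--noPS"], input=_norm_seq(seq).replace("T", "U"),
                         capture_output=True, text=True, check=True).stdout
    m = re.search(r"\(\s*(-?\d+\.?\d*)\)\s*$", out.strip().splitlines()[-1])
    if not m:
        raise RuntimeError(f"could not parse RNAfold output: {out!r}")
    return float(m.group(1))


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "intron_count", "mean_exon_length", "exon_dg", "ss_dg", "hi_score",
    "exac_variant_conservation", "exon_conservation", "gene_conservation",
    "ese_density", "ess_density", "esr_density",
    "mean_5ss_strength", "mean_3ss_strength",
    "exon_snp_density", "gene_snp_density",
    "cds_length", "gene_length", "mean_intron_length", "gc_content",
]

SS_FOLD_FLANK = 70  # nt up- and downstream of each splice site, folded as one window


def assemble_features(models: Mapping[str, GeneModel],
                      genome: Mapping[str, str],
                      tracks: Mapping[str, Mapping[str, float]] | None = None,
                      hexamers: HexamerTable | None = None,
                      pwm5: SpliceSitePWM | None = None,
                      pwm3: SpliceSitePWM | None = None,
                      fold_backend: Callable[[str], float] = stacking_fold_backend,
                      ) -> pd.DataFrame:
    """Assemble the 19-feature table, one row per intron-containing gene.

    ``tracks`` maps track name -> {gene_id: value} for the externally
    supplied per-gene scores: 'hi' (haploinsufficiency), 'exon_conservation',
    'gene_conservation', 'exac_variant_conservation', 'exon_snp_density',
    'gene_snp_density'. Missing haploinsufficiency scores are imputed with
    the cohort median (imputed genes recorded in ``df.attrs['imputed_hi']``);
    genes lacking sequence are dropped with a log entry. The result is
    deterministic and column-complete.
    """
    tracks = tracks or {}
    rows = []
    dropped = []
    for gid in sorted(models):
        g = models[gid]
        if g.n_introns == 0:
            continue
        if g.chrom not in genome:
            dropped.append(gid)
            continue
        chrom = genome[g.chrom]
        exon_seqs = [chrom[s:e] for s, e in g.exons]
        if g.strand == "-":
            exon_seqs = [_revcomp(s) for s in exon_seqs][::-1]
        all_exonic = "".join(exon_seqs)
        exon_lens = [e - s for s, e in g.exons]
        intron_lens = [g.exons[i + 1][0] - g.exons[i][1] for i in range(g.n_introns)]

        ss5_scores, ss3_scores, ss_dgs = [], [], []
        for kind, i in g.splice_sites():
            if kind == "5ss" and pwm5 is not None:
                ss5_scores.append(pwm5.score(site_sequence(g, kind, i, genome)))
            if kind == "3ss" and pwm3 is not None:
                ss3_scores.append(pwm3.score(site_sequence(g, kind, i, genome)))
            boundary = g.site_position(kind, i, 1)
            lo = max(0, boundary - SS_FOLD_FLANK)
            hi = min(len(chrom), boundary + SS_FOLD_FLANK)
            ss_dgs.append(fold_backend(chrom[lo:hi]))

        row = {
            "gene_id": gid,
            "intron_count": g.n_introns,
            "mean_exon_length": float(np.mean(exon_lens)),
            "exon_dg": float(np.mean([fold_backend(s) for s in exon_seqs])),
            "ss_dg": float(np.mean(ss_dgs)),
            "hi_score": tracks.get("hi", {}).get(gid, np.nan),
            "exac_variant_conservation": tracks.get("exac_variant_conservation", {}).get(gid, 0.0),
            "exon_conservation": tracks.get("exon_conservation", {}).get(gid, 0.0),
            "gene_conservation": tracks.get("gene_conservation", {}).get(gid, 0.0),
            "ese_density": _exonic_density(exon_seqs, hexamers, "ESE"),
            "ess_density": _exonic_density(exon_seqs, hexamers, "ESS"),
            "esr_density": _exonic_density(exon_seqs, hexamers, None),
            "mean_5ss_strength": float(np.mean(ss5_scores)) if ss5_scores else 0.0,
            "mean_3ss_strength": float(np.mean(ss3_scores)) if ss3_scores else 0.0,
            "exon_snp_density": tracks.get("exon_snp_density", {}).get(gid, 0.0),
            "gene_snp_density": tracks.get("gene_snp_density", {}).get(gid, 0.0),
            "cds_length": g.cds_length,
            "gene_length": g.gene_length,
            "mean_intron_length": float(np.mean(intron_lens)),
            "gc_content": (sum(all_exonic.upper().count(b) for b in "GC")
                           / max(len(all_exonic), 1)),
        }
        rows.append(row)
    if dropped:
        log.warning("dropped %d genes lacking sequence: %s", len(dropped), dropped[:5])
    df = pd.DataFrame(rows).set_index("gene_id")[FEATURE_COLUMNS]
    imputed = df.index[df["hi_score"].isna()].tolist()
    if imputed:
        known = df["hi_score"].dropna()
        df["hi_score"] = df["hi_score"].fillna(known.median() if len(known) else 0.5)
    df.attrs["imputed_hi"] = imputed
    if df.isna().any().any():
        raise AssertionError("feature table contains missing values after assembly")
    return df


def _exonic_density(exon_seqs: Sequence[str], table: HexamerTable | None,
                    hexamer_class: str | None) -> float:
    """Motif hits per exonic nucleotide; exons scanned separately (hexamers
    do not span exon junctions in the pre-mRNA)."""
    if table is None:
        return 0.0
    total_len = sum(len(s) for s in exon_seqs)
    if total_len == 0:
        return 0.0
    hits = sum(esr_density(s, table, hexamer_class) * len(s) for s in exon_seqs)
    return hits / total_len


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
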