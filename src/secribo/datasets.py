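"""Bundled study inputs: tissue selenium measurements and synthetic panels.

Two kinds of data live here.

*Measured tissue selenium concentrations* — the printed dietary-study means
(two diets x three tissues, N = 3 animals) used for the dietary-contrast
arithmetic: liver selenium drops roughly ten-fold on the selenium-deficient
diet.

*Synthetic transcriptome panels* — stylized selenoprotein transcript sets
with known per-gene abundance (theta) and UGA-Sec readthrough (rho) truth,
used by the simulator.  Gene names, relative liver abundances and Sec-codon
placements follow the mouse liver selenoproteome (C-terminal-Sec genes such
as Txnrd1 really are unanalyzable downstream of the Sec codon; Sepp1 carries
many Sec codons; Gapdh has none), but sequences are random and coordinates
are stylized: the panel is a synthetic stand-in, not RefSeq.

Calibration note: an RPKM fold change is a *relative* measure — scaling by
total mapped reads makes every fold carry a composition factor W0/W1, the
ratio of total transcriptional output between conditions.  For the five
genes with a stated target fold the panel therefore derives the supplemented
-diet readthrough rho1 by inverting the measurement model (fixed-point in
the composition factor) so that the *expected measured* 3' RPKM fold equals
the target; for all other genes rho1 is set directly.  Everything is a
closed-form consequence of the declared theta/rho/fold table below — nothing
is fitted to data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import SimulationConfig, make_transcript
from .transcriptome import TranscriptModel

CONDITIONS = ("0Se", "0.1Se")

# ---------------------------------------------------------------------------
# tissue selenium concentrations (mean, SEM; N = 3 per tissue per diet)
# liver/lung in ug/g, plasma in ug/mL
TISSUE_SELENIUM = pd.DataFrame(
    [
        ("liver", "0Se", 0.1065, 0.0143, "ug/g"),
        ("liver", "0.1Se", 1.0830, 0.0240, "ug/g"),
        ("lung", "0Se", 0.1096, 0.0129, "ug/g"),
        ("lung", "0.1Se", 0.3163, 0.0149, "ug/g"),
        ("plasma", "0Se", 0.0559, 0.0090, "ug/mL"),
        ("plasma", "0.1Se", 0.3510, 0.0078, "ug/mL"),
    ],
    columns=["tissue", "diet", "mean", "sem", "unit"],
)

#: selenium content of the two study diets (ppm, measured fluorometrically)
DIET_SELENIUM = {"0Se": 0.0238, "0.1Se": 0.128}


def tissue_selenium_ratio(tissue: str = "liver") -> float:
    """Fold difference in tissue selenium, supplemented over deficient."""
    t = TISSUE_SELENIUM.set_index(["tissue", "diet"])["mean"]
    return float(t[(tissue, "0.1Se")] / t[(tissue, "0Se")])


# ---------------------------------------------------------------------------
# selenoprotein panel
#
# columns: codons (CDS incl. stop), sec codon indices, theta0 (relative
# abundance on the deficient diet), mrna_fold (0.1Se/0Se), rho0, and either
# a target measured 3' RPKM fold (headline genes; rho1 derived) or rho1.
_PANEL = [
    # gene,   codons, sec,                      theta0, mfold, rho0, target, rho1
    ("Gpx1",    202, (47,),                      0.045, 4.0, 0.20, 15.0, None),
    ("Sepx1",   200, (40,),                      0.085, 1.3, 0.075, 13.0, None),
    ("Sepw1",   120, (13,),                      0.030, 3.0, 0.35, 6.0, None),
    ("Sephs2",  448, (60,),                      0.020, 1.0, 0.15, 5.0, None),
    ("Gpx4",    170, (73,),                      0.032, 1.1, 0.45, 1.9, None),
    ("Sepp1",   381, (59, 300, 318, 330, 345,
                      352, 360, 367, 372, 377), 0.020, 1.5, 0.30, None, 0.525),
    ("Txnrd1",  500, (498,),                     0.008, 1.1, 0.50, None, 0.65),
    ("Txnrd2",  524, (522,),                     0.003, 1.5, 0.50, None, 0.65),
    ("Selh",    123, (44,),                      0.006, 3.0, 0.30, None, 0.75),
    ("Selk",     95, (92,),                      0.006, 2.5, 0.40, None, 0.70),
    ("Selt",    196, (49,),                      0.004, 1.2, 0.40, None, 0.93),
    ("Sels",    190, (188,),                     0.005, 1.2, 0.45, None, 0.70),
    ("Sep15",   163, (93,),                      0.008, 1.1, 0.35, None, 0.89),
    ("Seli",    398, (387,),                     0.002, 1.1, 0.40, None, 0.80),
    ("Selo",    669, (665,),                     0.002, 1.2, 0.45, None, 0.70),
    ("Selm",    146, (48,),                      0.006, 1.2, 0.40, None, 0.93),
    ("Sepn1",   557, (428,),                     0.003, 1.2, 0.35, None, 0.82),
    ("Dio1",    258, (126,),                     0.006, 1.3, 0.30, None, 0.65),
    ("Dio2",    267, (133,),                     0.0005, 1.0, 0.30, None, 0.60),
    ("Dio3",    305, (144,),                     0.0005, 1.0, 0.30, None, 0.60),
    ("Gpx2",    191, (40,),                      0.001, 1.2, 0.30, None, 0.70),
    ("Gpx3",    227, (73,),                      0.006, 1.1, 0.35, None, 0.85),
    ("Txnrd3",  607, (605,),                     0.001, 1.1, 0.50, None, 0.65),
    ("Selv",    346, (273,),                     0.0005, 1.0, 0.30, None, 0.60),
    ("Gapdh",   334, (),                         0.060, 1.0, None, None, None),
]

#: abundant non-selenoprotein liver mRNAs; they dominate total mapped reads
#: so RPKM normalization behaves as with a genome-wide reference
_BACKGROUND = [
    ("Alb", 609, 0.30), ("Ttr", 148, 0.08), ("Apoa1", 265, 0.07),
    ("Fga", 434, 0.05), ("Serpina1", 414, 0.06), ("Trf", 698, 0.05),
    ("Apoe", 312, 0.05), ("Cyp2e1", 494, 0.03), ("Ahsg", 346, 0.03),
    ("Fabp1", 128, 0.04), ("Mup3", 181, 0.03), ("Tfrc", 450, 0.02),
    ("Hp", 348, 0.02), ("Car3", 261, 0.02),
]
_BACKGROUND_SCALE = 2.5

_PANEL_SEED = 20101  # fixes the synthetic reference sequences
HEADLINE_GENES = ("Gpx1", "Sepx1", "Sepw1", "Sephs2", "Gpx4")


def panel_table() -> pd.DataFrame:
    rows = [(g, n, ",".join(map(str, sec)), th, mf, r0, tgt, r1)
            for g, n, sec, th, mf, r0, tgt, r1 in _PANEL]
    return pd.DataFrame(rows, columns=[
        "gene", "codons", "sec_codons", "theta0", "mrna_fold", "rho0",
        "target_fold_3p", "rho1"])


def panel_transcripts() -> list[TranscriptModel]:
    """The synthetic selenoprotein + background transcript set."""
    rng = np.random.default_rng(_PANEL_SEED)
    out = []
    for i, (gene, n, sec, *_rest) in enumerate(_PANEL):
        utr5 = int(rng.integers(60, 150))
        utr3 = int(rng.integers(80, 300))
        out.append(make_transcript(rng, f"SYN_{i+1:03d}.1", gene, n, sec,
                                   utr5, utr3))
    for j, (gene, n, _th) in enumerate(_BACKGROUND):
        utr5 = int(rng.integers(60, 150))
        utr3 = int(rng.integers(80, 300))
        out.append(make_transcript(rng, f"SYN_{len(_PANEL)+j+1:03d}.1",
                                   gene, n, (), utr5, utr3))
    return out


def _footprint_weight(n_codons: int, sec: tuple[int, ...], theta: float,
                      rho: float | None) -> float:
    """Expected footprint weight of one gene (A-sites on codons 1..stop)."""
    n_sites = n_codons - 1
    if not sec:
        return theta * n_sites
    first = sec[0]
    return theta * (first + rho * (n_sites - first))


def _composition_ratio(rho1: dict[str, float]) -> float:
    """W0/W1: ratio of total footprint output, deficient over supplemented."""
    w0 = w1 = 0.0
    for gene, n, sec, th0, mf, r0, _tgt, _r1 in _PANEL:
        w0 += _footprint_weight(n, sec, th0, r0)
        w1 += _footprint_weight(n, sec, th0 * mf, rho1.get(gene))
    for gene, n, th in _BACKGROUND:
        w0 += th * _BACKGROUND_SCALE * (n - 1)
        w1 += th * _BACKGROUND_SCALE * (n - 1)
    return w0 / w1


def _calibrated_rho1() -> dict[str, float]:
    """Solve rho1 for target-fold genes (fixed point in the composition).

    measured fold = mrna_fold * (rho1/rho0) * W0/W1, so
    rho1 = rho0 * target / mrna_fold * (W1/W0); W depends on all rho1,
    hence a few fixed-point sweeps (converges geometrically).
    """
    rho1 = {g: r1 for g, _n, _s, _t, _m, _r0, tgt, r1 in _PANEL
            if r1 is not None}
    targets = [(g, r0, mf, tgt) for g, _n, _s, _t, mf, r0, tgt, _r1
               in _PANEL if tgt is not None]
    for g, r0, mf, tgt in targets:  # initial guess: no composition drift
        rho1[g] = r0 * tgt / mf
    for _ in range(8):
        comp = _composition_ratio(rho1)
        for g, r0, mf, tgt in targets:
            rho1[g] = r0 * tgt / mf / comp
    for g, v in rho1.items():
        if not 0.0 < v <= 1.0:
            raise ValueError(f"calibrated rho1 out of range for {g}: {v}")
    return rho1


def default_panel_config(seed: int = 1,
                         library_size: int = 1_000_000,
                         **overrides) -> SimulationConfig:
    """The default two-diet, two-replicate synthetic liver experiment."""
    rho1 = _calibrated_rho1()
    abundance: dict[str, dict[str, float]] = {}
    readthrough: dict[str, dict[str, float]] = {}
    for gene, _n, sec, th0, mf, r0, _tgt, _r1 in _PANEL:
        abundance[gene] = {"0Se": th0, "0.1Se": th0 * mf}
        if sec:
            readthrough[gene] = {"0Se": r0, "0.1Se": rho1[gene]}
    for gene, _n, th in _BACKGROUND:
        th = th * _BACKGROUND_SCALE
        abundance[gene] = {"0Se": th, "0.1Se": th}
    return SimulationConfig(
        transcripts=panel_transcripts(),
        abundance=abundance,
        readthrough=readthrough,
        seed=seed,
        library_size=library_size,
        **overrides,
    )


def expected_fold_3p() -> pd.Series:
    """Model-implied expected measured 3' RPKM fold per selenoprotein.

    mrna_fold * rho-fold * composition factor; NaN for genes without an
    analyzable 3' window.
    """
    rho1 = _calibrated_rho1()
    comp = _composition_ratio(rho1)
    out = {}
    for gene, n, sec, _th, mf, r0, _tgt, _r1 in _PANEL:
        if not sec:
            continue
        first = sec[0]
        if (n - 4) - (first + 2) + 1 <= 0:  # no 3' window
            out[gene] = np.nan
        else:
            out[gene] = mf * rho1[gene] / r0 * comp
    return pd.Series(out, name="expected_fold_3p")


def readthrough_grid_config(
    rhos=tuple(np.round(np.arange(0.05, 0.951, 0.05), 2)),
    seed: int = 1,
    library_size: int = 200_000,
    n_codons: int = 300,
    sec_codon: int = 150,
) -> SimulationConfig:
    """One-condition panel with one gene per readthrough value.

    Equal abundances and identical gene structure isolate the estimator:
    gene ``RT_05`` carries rho = 0.05, and so on across the grid.
    """
    rng = np.random.default_rng(_PANEL_SEED + 1)
    transcripts = []
    abundance = {}
    readthrough = {}
    for i, rho in enumerate(rhos):
        gene = f"RT_{int(round(rho * 100)):02d}"
        transcripts.append(make_transcript(
            rng, f"GRID_{i+1:03d}.1", gene, n_codons, (sec_codon,), 80, 80))
        abundance[gene] = {"grid": 1.0}
        readthrough[gene] = {"grid": float(rho)}
    return SimulationConfig(
        transcripts=transcripts,
        abundance=abundance,
        readthrough=readthrough,
        seed=seed,
        library_size=library_size,
        replicates=1,
        conditions=("grid",),
    )
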