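# chromassay

Quantitative analysis for the bench assays used to characterise
sperm-specific histone H2B variants ("spH2Bs") — histones whose extended
N-terminal tails carry tandem **SPKK motifs** (the tetrapeptide
SP(K/R)(K/R) that binds the DNA minor groove) and that replace canonical
H2B in sperm chromatin. The biological question behind these assays is
whether such variants stabilise chromatin and restrict its accessibility
without increasing compaction. The package is aimed at chromatin and
developmental-biology labs that quantify gels and micrographs by hand in
ImageJ and want the same recipes as scripted, tested, reproducible code.

## What it computes

- **Gel lane densitometry and digestion kinetics**
  (`chromassay.gel_profiles`): lanes are row-summed into intensity vs
  relative migration Rf ∈ [0, 1], background-subtracted from the
  Rf ≥ 0.97 region, and summarised by the *Rf of median band intensity* —
  the 50th percentile of the bottom-up cumulative signal, which is
  loading-independent. A restriction-digestion time course of median Rf
  is fitted to a saturating log-normal curve
  `rf(t) = baseline + amplitude·Φ((ln t − μ)/σ)`.
- **Nucleosomal repeat length (NRL)** (`chromassay.sizing`): a standard
  curve piecewise-linear in (Rf, log₁₀ size) is fitted to the mean
  migration of flanking ladder lanes; micrococcal-nuclease (MNase)
  digestion peaks are sized against it, and the NRL is the
  mean ± s.d. of sizeₙ/n over digestion fragments n = 2…7.
- **Melt-curve transitions** (`chromassay.melt`): maxima of the smoothed
  dF/dT of a thermal-stability dye-binding curve, classified into
  H2A-H2B dimer dissociation and DNA release.
- **Nuclei image quantification** (`chromassay.nucleim`): Kapur
  maximum-entropy and isodata (iterative intermeans) thresholding
  implemented from the histogram up, distance-transform watershed
  separation of touching nuclei by one-pixel lines, size-filtered
  particle counting, pixel-counted polygon areas, and two-channel
  ATAC-see accessible-fraction quantitation (|DNA ∧ ATAC| / |DNA|).
- **Motif scanning** (`chromassay.seqmotif`): counts and positions of
  SPKK-family motifs (SPKK/SPKR/SPRK/SPRR core; SPAKK separately) in
  protein FASTA records.
- **Statistics** (`chromassay.stats_report`): unpaired t-test, one-way
  ANOVA, mean ± s.d./s.e.m., and 1.5×IQR box-and-whisker summaries.
- **Synthetic data with ground truth** (`chromassay.synthio`): seeded
  generators for every input above — gels under the semi-log migration
  model rf = a − b·log₁₀(size), MNase ladders, digestion time courses,
  melt curves, two-channel nuclei fields, and motif-planted peptides —
  used to validate every pipeline end-to-end.

## Worked example

Recover a sperm-chromatin-like repeat length from a synthetic MNase gel,
and transition temperatures from a synthetic melt curve:

```python
from chromassay import melt, sizing, synthio
from chromassay.synthio import SynthConfig

img = synthio.make_mnase_ladder(
    nrl=225.0, n_max=8, cfg=SynthConfig(seed=1, noise_sd=0.1, sampling=1200)
)
est = sizing.analyze_mnase_gel(img, synthio.DEFAULT_LADDER)
print(f"NRL = {est.mean:.1f} ± {est.sd:.1f} bp")

curve = synthio.make_melt(
    [(70.0, 2.0, 1000.0), (89.0, 2.0, 1000.0)], (40.0, 99.0),
    SynthConfig(seed=3, noise_sd=20.0, sampling=1 / 0.3),
)
dimer, release, _ = melt.classify_transitions(
    melt.find_transitions(curve).transitions
)
print(f"dimer dissociation {dimer.tm:.1f} °C, DNA release {release.tm:.1f} °C")
```

prints

```
NRL = 225.1 ± 0.2 bp
dimer dissociation 70.0 °C, DNA release 89.0 °C
```

i.e. the fragments-2–7 estimator recovers the generated 225 bp repeat
(a sperm-like value; somatic chromatin sits near 207 bp), and the
derivative-maximum caller places the H2A-H2B dimer-dissociation and DNA
release transitions at their generated centres.

The same pipelines are scriptable from the shell, e.g.:

```sh
chromassay simulate mnase --config mnase.json --seed 1 --out sim/
chromassay nrl --image sim/mnase.tif --lanes lanes.json \
    --ladder-sizes 100,200,300,400,500,700,1000,1500,2000 --out nrl.csv
chromassay melt --curve melt.csv --out transitions.csv
chromassay count --image field_dna.tif --method isodata --min-size 100 --out particles.csv
```

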