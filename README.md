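# lc8motif

Position-specific scoring and proteome scanning of LC8 dynein-light-chain
binding motifs in intrinsically disordered protein regions.

## The problem

LC8 (DYNLL1) is an 89-residue homodimeric hub protein that binds dozens of
partners through a short linear motif in their disordered regions: eight
residues, numbered −5..+2, anchored by a Thr-Gln-Thr triplet at positions
−1..+1 ("TQT", with variants such as SQT, TQI or the Myosin Va TMT).  The
anchor is necessary but far from sufficient — many anchor-containing
peptides show no binding by isothermal titration calorimetry — so
recognizing real binding sites requires the flanking positions too.
`lc8motif` is for molecular and computational biologists who want to score
candidate 8-mers or scan whole protein sequences for likely LC8 sites.

## The method

From a curated training set of 79 binder motifs and 32 anchor-containing
nonbinder motifs, six log₂-ratio position weight matrices are built — for
each symbol scheme *s* ∈ {amino acid, polarity bin, volume bin}:

- a background-normalized matrix
  `W_bg(c, p) = log2( f_bind(c, p) / f_bg(c) )`, where `f_bg` is the
  residue composition of disordered regions, and
- a nonbinder-normalized matrix
  `W_nb(c, p) = log2( f_bind(c, p) / f_nonbind(c, p) )`, whose anchor
  columns (−1, 0, +1) are zeroed because the nonbinders were selected to
  contain anchors and carry no signal there.

Frequencies use an add-α pseudocount (α = 1 per category).  The polarity
bins are positively charged / negatively charged / polar-uncharged /
nonpolar; the volume bins follow four published residue-volume ranges
(<106, 122–142, 155–171, >200 Å³).  Two scores summarize a window *m*:

    S_aa(m) = Σ_p  w₁·W_id_bg(m_p, p) + w₂·W_id_nb(m_p, p)
    S_vp(m) = Σ_p  w₃·W_vol_bg(v(m_p), p) + w₄·W_vol_nb(v(m_p), p) + w₅·W_pol_nb(π(m_p), p)

(the binder-only polarity matrix is excluded from `S_vp`; dropping it
maximized the cross-validated ROC area).  The weights `w` are chosen by a
grid search maximizing the leave-one-out (LOO) ROC AUC, and the decision
thresholds are calibrated on the LOO score cloud: a window is called a
**binder** when `S_aa ≥ θ_aa` and `S_vp ≥ θ_vp`, and **high-confidence**
when `S_vp ≥ θ_hc` alone, with `θ_hc` the smallest threshold giving zero
LOO false positives.  Scanning slides the 8-residue window along a
sequence, reports the anchor-slot coordinate of each hit, and can filter
hits whose mean disorder propensity (from an external per-residue track)
falls below 0.5.

## Worked example

```python
from lc8motif import MotifBindingClassifier, load_packaged_training
from lc8motif.scoring import score_motif, classify

training = load_packaged_training()
clf = MotifBindingClassifier().fit(
    training.binder_motifs + training.nonbinder_motifs,
    ["binder"] * 79 + ["nonbinder"] * 32,
)
print({k: round(v, 2) for k, v in clf.thresholds_.items()})
for motif in ["CDKSTQTP", "LDQPTQTV", "AAAAAAAA"]:
    pair = score_motif(motif, clf.matrix_set_)
    print(motif, round(pair.s_aa, 2), round(pair.s_vp, 2),
          classify(pair, clf.matrix_set_))
```

prints

```
{'theta_aa': 14.49, 'theta_vp': 2.99, 'theta_hc': 3.81}
CDKSTQTP 39.75 5.49 high_confidence
LDQPTQTV 12.18 1.61 nonbinder
AAAAAAAA -26.92 -8.27 nonbinder
```

`CDKSTQTP` is the BCL2L11 motif, the tightest binder in the training data
(K_d 0.16 μM): both scores clear their thresholds and `S_vp` alone exceeds
the zero-false-positive threshold, so it lands in the high-confidence
tier.  `LDQPTQTV` is an anchor-containing nonbinder (a hydrophobic valine
at the exposed +2 position is strongly disfavored) and is rejected despite
its TQT.  An anchor-free poly-alanine window scores far below zero on
every matrix.

The fitted LOO operating point on the packaged training table is
fp = 2, fn = 20 (accuracy 80.2 %, TPR 74.7 %, TNR 93.8 %), with LOO AUCs
of 0.987 (`S_aa`) and 0.942 (`S_vp`); the high-confidence tier retains
67 % of binders at a 0 % false-positive rate.

Command line:

```bash
lc8motif train --out-dir matrices/          # six PSSM TSVs + config.yaml
lc8motif evaluate --out loo_report.tsv      # per-motif LOO scores + summary JSON
lc8motif scan proteins.fasta --out hits.tsv --disorder tracks.tsv
```

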