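# Packaged data fixtures

All fixtures are plain TSV regenerated by `scripts/make_training_fixture.py`
and `scripts/freeze_config.py`; none are downloaded at run time.

## table1_synthetic.tsv / table2_synthetic.tsv

Transcriptions of the two curated peptide tables behind the training data:
ITC-tested phage-display hits (47 rows: 12 binder, 4 weak-binder, 31
nonbinder) and ITC-tested PSSM-predicted candidates (19 rows: 7 binder, 12
nonbinder).  Conventions:

- Non-native solubility/concentration residues (terminal D/Y additions on
  some synthesized peptides) are stripped; `q_index` refers to the
  stripped sequence.
- `q_index` is the 1-based anchor-glutamine slot.  Rows whose peptide has
  no anchor triplet under the extended pattern `[STIV][QM][STIV]`, or
  whose anchor sits too close to a terminus for a full −5..+2 window,
  carry a **surrogate** `q_index` (the most central glutamine with full
  flanks, else position 6) so that every record loads; these rows are
  never used for matrix training.  Surrogate rows: BSN-shift, IRS1,
  CRYBG1, DAZL (first table), MUC5B-1, PLK1, KY, PPP2R3A, CUL3, SAV1,
  MSTL1, DMRTA2, OTOG, ZNF469, DNLJ2, ILK, EIF4G3.
- Two peptide pairs are independent syntheses of the same native motif
  (MUC4 with/without a solubility tag; SCRN2 likewise).  Both rows are
  kept; matrix training deduplicates on (protein_id, motif).
- Dissociation constants are included only where individually published
  (BCL2L11 0.16 uM; rotavirus VP4 4.2 uM).

## training_table_synthetic.tsv

The 79-binder / 32-nonbinder training table.  44 motifs are real:

- 19 binders: the 11 unique anchored binder motifs of the first table,
  the 7 of the second, and the Myosin Va TMT-anchor motif `DDKNTMTD`
  (flanking context unpublished, so its peptide equals the 8-mer).
- 25 nonbinders: every anchor-containing nonbinder motif with full
  −5..+2 flanks (16 from the first table, 9 from the second).

The remaining rows stand in for a curated supplement that is not
redistributable here: 60 binders (`SYNB*`) and 7 nonbinders (`SYNN*`) are
SYNTHETIC, drawn once with a fixed seed (20260901) from the per-position
residue frequencies of the transcribed motifs of the same class (no
pseudocount, so only residues observed at a position are sampled and every
stand-in keeps a valid anchor).  Count-based tests assert against this
manifest: 79 binders, 32 nonbinders, of which 44 motifs real.

## background_disorder_synthetic.tsv

SYNTHETIC stand-in for a disordered-region residue background derived
from a curated disorder database: disorder-promoting residues
(P, E, S, K, Q, G) enriched, order-promoting ones (W, C, F, Y, I, L, V)
depleted; sums to 1.

## residue_volumes.tsv

Zamyatnin mean residue volumes with the four-bin assignment used by the
volume scheme (gap residues assigned to the nearest printed range
boundary).

## config.yaml

Frozen output of the training pipeline on the packaged table: the
grid-searched combination weights, the calibrated thresholds on this
score scale, and (for reference) the published thresholds on the original
score scale.
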