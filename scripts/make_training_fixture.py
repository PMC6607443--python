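"""Regenerate the packaged motif-table fixtures.

Three TSVs are written into ``src/lc8motif/data/``:

* ``table1_synthetic.tsv`` / ``table2_synthetic.tsv`` — transcriptions of
  the two printed peptide tables (ITC-tested phage-display hits and
  PSSM-predicted candidates).  Solubility/concentration residues added to
  the synthetic peptides (terminal D/Y additions) are stripped and
  ``q_index`` refers to the stripped sequence.  Rows whose peptide has no
  anchor triplet, or whose anchor sits too close to a terminus for a full
  -5..+2 window, carry a documented surrogate ``q_index`` (the most
  central glutamine slot, else position 6).
* ``training_table_synthetic.tsv`` — the 79-binder / 32-nonbinder training
  table.  44 of its motifs are the printed ones (19 binders incl. the
  Myosin Va TMT outlier; 25 anchor-containing nonbinders with full
  flanks); the supplementary rows it stands in for are not printed, so the
  remaining 60 binders and 7 nonbinders are SYNTHETIC stand-ins drawn
  once, seed-fixed, from per-position residue frequencies of the
  transcribed motifs of the same class (no pseudocount, so only observed
  residues are sampled and every stand-in keeps a valid anchor).

Run from the repository root:  python scripts/make_training_fixture.py
"""

from __future__ import annotations

import sys
from collections import Counter
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from lc8motif.alphabet import MOTIF_LENGTH
from lc8motif.datasets import EXTENDED_ANCHOR, MotifRecord, find_anchor

DATA = Path(__file__).resolve().parents[1] / "src" / "lc8motif" / "data"
STANDIN_SEED = 20260901  # fixed once; the fixture is frozen text

# (protein_id, gene, peptide_stripped, q_index, label, kd_um, surrogate_q)
TABLE1 = [
    ("O43521", "BCL2L11", "APMSCDKSTQTPSP", 10, "binder", 0.16, False),
    ("Q9UPA5", "BSN", "PRATAEFSTQTPSP", 10, "binder", None, False),
    ("Q86VQ1", "GLCCI1", "SSSTRSIDTQTPSV", 10, "binder", None, False),
    ("Q96R06", "SPAG5", "HPETQDSSTQTDTS", 10, "binder", None, False),
    ("Q6IMN6", "CAPRIN2", "NQSFTTASTQTPPQ", 10, "binder", None, False),
    ("O75665", "OFD1", "AKESCNMETQTSST", 10, "binder", None, False),
    ("Q02505", "MUC3A", "PVLTSATGTQTSPA", 10, "binder", None, False),
    ("Q9UBY0", "SLC9A2", "HSREKGTQTSG", 8, "binder", None, False),
    ("Q9Y2F5", "ICE1", "EKELRHIGTQISSD", 10, "binder", None, False),
    ("Q9ULV3", "CIZ1", "ARAGRSVSTQTGSM", 10, "binder", None, False),
    ("Q99102", "MUC4", "SQNHWTRSTQTTRE", 10, "binder", None, False),
    ("Q99102", "MUC4", "NHWTRSTQTTRE", 8, "binder", None, False),
    ("P07359", "GP1BA", "GQGAALTTATQTTHLE", 11, "weak_binder", None, False),
    ("Q9Y4F4", "TOGARAM1", "SKTQQTFGSQTECT", 10, "weak_binder", None, False),
    ("Q8WWN8", "ARAP3", "SPSPTGLPTQTPGF", 10, "weak_binder", None, False),
    ("Q01973", "ROR1", "SGGNATTQTTS", 8, "weak_binder", None, False),
    ("Q8NEZ4", "KMT2C", "IVSCVSVSTQTASD", 10, "nonbinder", None, False),
    ("Q9UPA5", "BSN-shift", "STQTPSPAPASDMP", 6, "nonbinder", None, True),
    ("Q7Z2Z2", "EFL1", "ERLMCTGSQTFD", 9, "nonbinder", None, False),
    ("Q02817", "MUC2", "TPTPTPTGTQTPTT", 10, "nonbinder", None, False),
    ("Q9HC84", "MUC5B-3", "SMATPSSSTQTSGT", 10, "nonbinder", None, False),
    ("Q8TEC5", "SH3RF2", "TLVSTASGTQTVFP", 10, "nonbinder", None, False),
    ("Q9P2G1", "ANKIB1", "RGDGSDVSSQTPQT", 10, "nonbinder", None, False),
    ("O43526", "KCNQ2", "PMYSSQTQTYG", 8, "nonbinder", None, False),
    ("P14859", "POU2F1", "ESGDGNTGTQTNGL", 10, "nonbinder", None, False),
    ("P35568", "IRS1", "LPRKVDTAAQTNSR", 10, "nonbinder", None, True),
    ("Q2KHR3", "QSER1", "KTLTFSGSSQTVTP", 10, "nonbinder", None, False),
    ("Q99814", "EPAS1", "TEAKDQCSTQTDFN", 10, "nonbinder", None, False),
    ("Q9Y4K1", "CRYBG1", "RSFVLPVESTQDVSSQ", 11, "nonbinder", None, True),
    ("P49862", "KLK7", "SFRHPGYSTQTHVN", 10, "nonbinder", None, False),
    ("Q92904", "DAZL", "TQDDYFKDKRVHHFRRS", 6, "nonbinder", None, True),
    ("Q96FV2", "SCRN2", "VRTLPRFQTQVDRR", 10, "nonbinder", None, False),
    ("Q96FV2", "SCRN2", "TLPRFQTQVDRR", 8, "nonbinder", None, False),
    ("Q7Z589", "EMSY", "KITFTKPSTQTTNT", 10, "nonbinder", None, False),
    ("Q13952", "NFYC", "CLKETLQITQTEVQ", 10, "nonbinder", None, False),
    ("Q9HC84", "MUC5B-1", "TTLPVLTSTATKST", 6, "nonbinder", None, True),
    ("P53350", "PLK1", "AASLIQKMLQTDPTAR", 10, "nonbinder", None, True),
    ("Q92499", "DDX1", "HSGNAQVTQTKF", 9, "nonbinder", None, False),
    ("Q8NBH2", "KY", "ITSYNSQGTQLTVE", 10, "nonbinder", None, True),
    ("Q06190", "PPP2R3A", "LQETLTTSSQANLS", 10, "nonbinder", None, True),
    ("Q13618", "CUL3", "KHSGRQLTLQHHMG", 10, "nonbinder", None, True),
    ("Q9H4B6", "SAV1", "NQSFLRTPIQRTPH", 10, "nonbinder", None, True),
    ("Q2TV78", "MSTL1", "EGYRGTANTTTAAYLA", 6, "nonbinder", None, True),
    ("Q6ZU65", "UBN2", "PLQATISKSQTNPV", 10, "nonbinder", None, False),
    ("Q96SC8", "DMRTA2", "SSRSAFSPLQPNAS", 10, "nonbinder", None, True),
    ("Q6ZRI0", "OTOG", "TLQQPLELTASQLPAG", 12, "nonbinder", None, True),
    ("Q96JG9", "ZNF469", "RAAALPEETRSSRR", 6, "nonbinder", None, True),
]

TABLE2 = [
    ("Q6LCS3", "E4_HPV", "LQGRQEDKQTQTPPP", 11, "binder", None, False),
    ("Q8IX07", "ZFPM1", "PAPPSYSDKGVQTPSK", 12, "binder", None, False),
    ("P11193", "VP4_RVA", "VTNSLNDISTQTSTI", 11, "binder", 4.2, False),
    ("P13500", "CCL2", "DSMDHLDKQTQTPKT", 11, "binder", None, False),
    ("P18583", "SON", "SRKSRCVSVQTDPT", 10, "binder", None, False),
    ("Q9Y2H9", "MAST1", "GCTRHQSVQTEDG", 9, "binder", None, False),
    ("P80098", "CCL7", "QDFMKHLDKKTQTPKL", 12, "binder", None, False),
    ("Q5K4E3", "PRSS36", "GPDGEETETQTCPP", 10, "nonbinder", None, False),
    ("P20702", "ITGAX", "GQIAPENGTQTPSP", 10, "nonbinder", None, False),
    ("P03586", "MT_TMV", "AQPKQKLDTSIQTEYP", 12, "nonbinder", None, False),
    ("Q8IYH5", "ZZZ3", "KSVAENGDTDTQTSMF", 12, "nonbinder", None, False),
    ("Q5DMI6", "DNLJ2_T5", "KIEIPTQCPSCGSK", 7, "nonbinder", None, True),
    ("Q92904", "DAZL", "PQKKSVDRSIQTVVS", 11, "nonbinder", None, False),
    ("Q9NZ56", "FMN2", "HHRILEAKSIQTSPT", 11, "nonbinder", None, False),
    ("Q13418", "ILK", "MDDIFTQCREGN", 7, "nonbinder", None, True),
    ("O43432", "EIF4G3", "DFTPAFADFGRQTPGG", 12, "nonbinder", None, True),
    ("Q99613", "EIF3C", "ELMASLDQPTQTVVM", 11, "nonbinder", None, False),
    ("O15444", "CCL25", "NKVFAKLHHNTQTFQA", 12, "nonbinder", None, False),
    ("P20042", "EIF2S2", "KPFMLDEEGDTQTEET", 12, "nonbinder", None, False),
]

# The Myosin Va TMT-anchor binder named in the text; its flanking context
# is not printed, so the peptide equals the 8-mer motif.
MYO5A = ("Q9Y4I1", "MYO5A", "DDKNTMTD", 6, "binder", None, False)

HEADER = "protein_id\tgene\tpeptide\tq_index\tlabel\tkd_um\tsource"


def rows_to_tsv(rows, source):
    out = []
    for pid, gene, pep, q, label, kd, _surrogate in rows:
        kd_s = "" if kd is None else str(kd)
        out.append(f"{pid}\t{gene}\t{pep}\t{q}\t{label}\t{kd_s}\t{source}")
    return out


def real_training_rows():
    """Printed rows usable for training: anchored, full flanks, deduplicated."""
    binders, nonbinders = [], []
    seen = set()
    for rows, source in ((TABLE1, "Table1"), (TABLE2, "Table2")):
        for pid, gene, pep, q, label, kd, surrogate in rows:
            if surrogate or label == "weak_binder":
                continue
            rec = MotifRecord(pid, gene, pep, q, label, kd, source)
            anchors = find_anchor(pep, EXTENDED_ANCHOR)
            if q not in anchors:
                continue
            key = (pid, rec.motif)
            if key in seen:
                continue
            seen.add(key)
            (binders if label == "binder" else nonbinders).append((rec, source))
    rec = MotifRecord(*MYO5A[:6], "LC8Hub")
    binders.append((rec, "LC8Hub"))
    return binders, nonbinders


def positional_sampler(motifs, rng):
    """Draw 8-mers from the per-position residue frequencies of ``motifs``."""
    columns = []
    for p in range(MOTIF_LENGTH):
        counts = Counter(m[p] for m in motifs)
        residues = sorted(counts)
        probs = np.array([counts[a] for a in residues], dtype=float)
        probs /= probs.sum()
        columns.append((residues, probs))

    def draw():
        return "".join(
            residues[rng.choice(len(residues), p=probs)]
            for residues, probs in columns
        )

    return draw


def make_standins(n, prefix, motifs, forbidden, rng):
    draw = positional_sampler(motifs, rng)
    out, used = [], set(forbidden)
    i = 0
    while len(out) < n:
        motif = draw()
        if motif in used:
            continue
        used.add(motif)
        i += 1
        out.append((f"SYN{prefix}{i:02d}", "synthetic", motif, 6))
    return out


def main():
    lines1 = ["# Transcription of the printed phage-display peptide table.",
              "# Rows marked in the manifest carry surrogate q_index values.",
              HEADER] + rows_to_tsv(TABLE1, "Table1")
    (DATA / "table1_synthetic.tsv").write_text("\n".join(lines1) + "\n")

    lines2 = ["# Transcription of the printed PSSM-predicted peptide table.",
              HEADER] + rows_to_tsv(TABLE2, "Table2")
    (DATA / "table2_synthetic.tsv").write_text("\n".join(lines2) + "\n")

    binders, nonbinders = real_training_rows()
    b_motifs = [r.motif for r, _ in binders]
    nb_motifs = [r.motif for r, _ in nonbinders]
    print(f"real binders: {len(binders)}, real nonbinders: {len(nonbinders)}")

    rng = np.random.default_rng(STANDIN_SEED)
    all_real = set(b_motifs) | set(nb_motifs)
    b_standins = make_standins(79 - len(binders), "B", b_motifs, all_real, rng)
    nb_forbidden = all_real | {m for _, _, m, _ in b_standins}
    nb_standins = make_standins(32 - len(nonbinders), "N", nb_motifs, nb_forbidden, rng)

    lines = [
        "# Training table: 79 binder and 32 anchor-containing nonbinder motifs.",
        "# Rows with protein_id SYN* are SYNTHETIC stand-ins for unprinted",
        "# supplementary rows, drawn seed-fixed from per-position residue",
        "# frequencies of the transcribed motifs of the same class",
        f"# (seed {STANDIN_SEED}).  See data/MANIFEST.md.",
        HEADER,
    ]
    for rec, source in binders:
        kd_s = "" if rec.kd_um is None else str(rec.kd_um)
        lines.append(f"{rec.protein_id}\t{rec.gene}\t{rec.peptide}\t{rec.q_index}\tbinder\t{kd_s}\t{source}")
    for pid, gene, motif, q in b_standins:
        lines.append(f"{pid}\t{gene}\t{motif}\t{q}\tbinder\t\tLC8Hub")
    for rec, source in nonbinders:
        lines.append(f"{rec.protein_id}\t{rec.gene}\t{rec.peptide}\t{rec.q_index}\tnonbinder\t\t{source}")
    for pid, gene, motif, q in nb_standins:
        lines.append(f"{pid}\t{gene}\t{motif}\t{q}\tnonbinder\t\tTableS4")
    (DATA / "training_table_synthetic.tsv").write_text("\n".join(lines) + "\n")
    print(f"wrote training table: {len(binders) + len(b_standins)} binders, "
          f"{len(nonbinders) + len(nb_standins)} nonbinders")


if __name__ == "__main__":
    main()
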