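# Training table: 79 binder and 32 anchor-containing nonbinder motifs.
# Rows with protein_id SYN* are SYNTHETIC stand-ins for unprinted
# supplementary rows, drawn seed-fixed from per-position residue
# frequencies of the transcribed motifs of the same class
# (seed 20260901).  See data/MANIFEST.md.
protein_id	gene	peptide	q_index	label	kd_um	source
O43521	BCL2L11	APMSCDKSTQTPSP	10	binder	0.16	Table1
Q9UPA5	BSN	PRATAEFSTQTPSP	10	binder		Table1
Q86VQ1	GLCCI1	SSSTRSIDTQTPSV	10	binder		Table1
Q96R06	SPAG5	HPETQDSSTQTDTS	10	binder		Table1
Q6IMN6	CAPRIN2	NQSFTTASTQTPPQ	10	binder		Table1
O75665	OFD1	AKESCNMETQTSST	10	binder		Table1
Q02505	MUC3A	PVLTSATGTQTSPA	10	binder		Table1
Q9UBY0	SLC9A2	HSREKGTQTSG	8	binder		Table1
Q9Y2F5	ICE1	EKELRHIGTQISSD	10	binder		Table1
Q9ULV3	CIZ1	ARAGRSVSTQTGSM	10	binder		Table1
Q99102	MUC4	SQNHWTRSTQTTRE	10	binder		Table1
Q6LCS3	E4_HPV	LQGRQEDKQTQTPPP	11	binder		Table2
Q8IX07	ZFPM1	PAPPSYSDKGVQTPSK	12	binder		Table2
P11193	VP4_RVA	VTNSLNDISTQTSTI	11	binder	4.2	Table2
P13500	CCL2	DSMDHLDKQTQTPKT	11	binder		Table2
P18583	SON	SRKSRCVSVQTDPT	10	binder		Table2
Q9Y2H9	MAST1	GCTRHQSVQTEDG	9	binder		Table2
P80098	CCL7	QDFMKHLDKKTQTPKL	12	binder		Table2
Q9Y4I1	MYO5A	DDKNTMTD	6	binder		LC8Hub
SYNB01	synthetic	REKGTMTP	6	binder		LC8Hub
SYNB02	synthetic	ATKSTQTP	6	binder		LC8Hub
SYNB03	synthetic	RHADTQTP	6	binder		LC8Hub
SYNB04	synthetic	RDINVQTP	6	binder		LC8Hub
SYNB05	synthetic	RDRGVQTP	6	binder		LC8Hub
SYNB06	synthetic	RAMKTQTE	6	binder		LC8Hub
SYNB07	synthetic	CNVDVQTP	6	binder		LC8Hub
SYNB08	synthetic	CDSSTQTD	6	binder		LC8Hub
SYNB09	synthetic	ADSDTQTP	6	binder		LC8Hub
SYNB10	synthetic	WTKSVQTP	6	binder		LC8Hub
SYNB11	synthetic	QEMSTQTS	6	binder		LC8Hub
SYNB12	synthetic	RCVSTQTP	6	binder		LC8Hub
SYNB13	synthetic	CTVKTQTP	6	binder		LC8Hub
SYNB14	synthetic	SDISTQTS	6	binder		LC8Hub
SYNB15	synthetic	CHVSTQTE	6	binder		LC8Hub
SYNB16	synthetic	WHSGTQTS	6	binder		LC8Hub
SYNB17	synthetic	CHKQTQTE	6	binder		LC8Hub
SYNB18	synthetic	LDISTQTD	6	binder		LC8Hub
SYNB19	synthetic	CTIGTQTP	6	binder		LC8Hub
SYNB20	synthetic	LNKETQTS	6	binder		LC8Hub
SYNB21	synthetic	DCKGTQTP	6	binder		LC8Hub
SYNB22	synthetic	WHASTQTE	6	binder		LC8Hub
SYNB23	synthetic	DDRETQTS	6	binder		LC8Hub
SYNB24	synthetic	LSKGTQTP	6	binder		LC8Hub
SYNB25	synthetic	LSMGTQTS	6	binder		LC8Hub
SYNB26	synthetic	DDIGTQIS	6	binder		LC8Hub
SYNB27	synthetic	NTRSVQTP	6	binder		LC8Hub
SYNB28	synthetic	RDISVQTS	6	binder		LC8Hub
SYNB29	synthetic	RDKSTQTS	6	binder		LC8Hub
SYNB30	synthetic	RDQSTMTS	6	binder		LC8Hub
SYNB31	synthetic	LDKGTQTP	6	binder		LC8Hub
SYNB32	synthetic	CTKGTQTP	6	binder		LC8Hub
SYNB33	synthetic	ADMKTQTP	6	binder		LC8Hub
SYNB34	synthetic	TTKSTQTS	6	binder		LC8Hub
SYNB35	synthetic	NSKSTQTP	6	binder		LC8Hub
SYNB36	synthetic	SEMSTQTT	6	binder		LC8Hub
SYNB37	synthetic	SHRGTQTG	6	binder		LC8Hub
SYNB38	synthetic	NTSSTQTT	6	binder		LC8Hub
SYNB39	synthetic	REVQVQTS	6	binder		LC8Hub
SYNB40	synthetic	CDVDTQTD	6	binder		LC8Hub
SYNB41	synthetic	QCKNTQTP	6	binder		LC8Hub
SYNB42	synthetic	RHIKTQTD	6	binder		LC8Hub
SYNB43	synthetic	NDSSTQTS	6	binder		LC8Hub
SYNB44	synthetic	AESEVQTP	6	binder		LC8Hub
SYNB45	synthetic	RSRNTQTS	6	binder		LC8Hub
SYNB46	synthetic	DEVSTQTS	6	binder		LC8Hub
SYNB47	synthetic	RTMDTQTP	6	binder		LC8Hub
SYNB48	synthetic	QDTQTQTD	6	binder		LC8Hub
SYNB49	synthetic	RDISVQTT	6	binder		LC8Hub
SYNB50	synthetic	RAASTQTS	6	binder		LC8Hub
SYNB51	synthetic	LDKNVQTP	6	binder		LC8Hub
SYNB52	synthetic	TCKSTQTP	6	binder		LC8Hub
SYNB53	synthetic	RSKQTQTP	6	binder		LC8Hub
SYNB54	synthetic	WDRDTQTE	6	binder		LC8Hub
SYNB55	synthetic	CSMSVQTP	6	binder		LC8Hub
SYNB56	synthetic	LDVETQTP	6	binder		LC8Hub
SYNB57	synthetic	REVKTQTP	6	binder		LC8Hub
SYNB58	synthetic	WDMSTQTD	6	binder		LC8Hub
SYNB59	synthetic	LDISTQTP	6	binder		LC8Hub
SYNB60	synthetic	LTMSVQTP	6	binder		LC8Hub
Q8NEZ4	KMT2C	IVSCVSVSTQTASD	10	nonbinder		Table1
Q7Z2Z2	EFL1	ERLMCTGSQTFD	9	nonbinder		Table1
Q02817	MUC2	TPTPTPTGTQTPTT	10	nonbinder		Table1
Q9HC84	MUC5B-3	SMATPSSSTQTSGT	10	nonbinder		Table1
Q8TEC5	SH3RF2	TLVSTASGTQTVFP	10	nonbinder		Table1
Q9P2G1	ANKIB1	RGDGSDVSSQTPQT	10	nonbinder		Table1
O43526	KCNQ2	PMYSSQTQTYG	8	nonbinder		Table1
P14859	POU2F1	ESGDGNTGTQTNGL	10	nonbinder		Table1
Q2KHR3	QSER1	KTLTFSGSSQTVTP	10	nonbinder		Table1
Q99814	EPAS1	TEAKDQCSTQTDFN	10	nonbinder		Table1
P49862	KLK7	SFRHPGYSTQTHVN	10	nonbinder		Table1
Q96FV2	SCRN2	VRTLPRFQTQVDRR	10	nonbinder		Table1
Q7Z589	EMSY	KITFTKPSTQTTNT	10	nonbinder		Table1
Q13952	NFYC	CLKETLQITQTEVQ	10	nonbinder		Table1
Q92499	DDX1	HSGNAQVTQTKF	9	nonbinder		Table1
Q6ZU65	UBN2	PLQATISKSQTNPV	10	nonbinder		Table1
Q5K4E3	PRSS36	GPDGEETETQTCPP	10	nonbinder		Table2
P20702	ITGAX	GQIAPENGTQTPSP	10	nonbinder		Table2
P03586	MT_TMV	AQPKQKLDTSIQTEYP	12	nonbinder		Table2
Q8IYH5	ZZZ3	KSVAENGDTDTQTSMF	12	nonbinder		Table2
Q92904	DAZL	PQKKSVDRSIQTVVS	11	nonbinder		Table2
Q9NZ56	FMN2	HHRILEAKSIQTSPT	11	nonbinder		Table2
Q99613	EIF3C	ELMASLDQPTQTVVM	11	nonbinder		Table2
O15444	CCL25	NKVFAKLHHNTQTFQA	12	nonbinder		Table2
P20042	EIF2S2	KPFMLDEEGDTQTEET	12	nonbinder		Table2
SYNN01	synthetic	LDVITQTE	6	nonbinder		TableS4
SYNN02	synthetic	LEGSSQTS	6	nonbinder		TableS4
SYNN03	synthetic	LDTSSQTT	6	nonbinder		TableS4
SYNN04	synthetic	TCVQIQTS	6	nonbinder		TableS4
SYNN05	synthetic	FESVTQTV	6	nonbinder		TableS4
SYNN06	synthetic	SSTDTQTK	6	nonbinder		TableS4
SYNN07	synthetic	DEKGTQTE	6	nonbinder		TableS4
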