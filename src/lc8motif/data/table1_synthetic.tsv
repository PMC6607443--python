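# Transcription of the printed phage-display peptide table.
# Rows marked in the manifest carry surrogate q_index values.
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
Q99102	MUC4	NHWTRSTQTTRE	8	binder		Table1
P07359	GP1BA	GQGAALTTATQTTHLE	11	weak_binder		Table1
Q9Y4F4	TOGARAM1	SKTQQTFGSQTECT	10	weak_binder		Table1
Q8WWN8	ARAP3	SPSPTGLPTQTPGF	10	weak_binder		Table1
Q01973	ROR1	SGGNATTQTTS	8	weak_binder		Table1
Q8NEZ4	KMT2C	IVSCVSVSTQTASD	10	nonbinder		Table1
Q9UPA5	BSN-shift	STQTPSPAPASDMP	6	nonbinder		Table1
Q7Z2Z2	EFL1	ERLMCTGSQTFD	9	nonbinder		Table1
Q02817	MUC2	TPTPTPTGTQTPTT	10	nonbinder		Table1
Q9HC84	MUC5B-3	SMATPSSSTQTSGT	10	nonbinder		Table1
Q8TEC5	SH3RF2	TLVSTASGTQTVFP	10	nonbinder		Table1
Q9P2G1	ANKIB1	RGDGSDVSSQTPQT	10	nonbinder		Table1
O43526	KCNQ2	PMYSSQTQTYG	8	nonbinder		Table1
P14859	POU2F1	ESGDGNTGTQTNGL	10	nonbinder		Table1
P35568	IRS1	LPRKVDTAAQTNSR	10	nonbinder		Table1
Q2KHR3	QSER1	KTLTFSGSSQTVTP	10	nonbinder		Table1
Q99814	EPAS1	TEAKDQCSTQTDFN	10	nonbinder		Table1
Q9Y4K1	CRYBG1	RSFVLPVESTQDVSSQ	11	nonbinder		Table1
P49862	KLK7	SFRHPGYSTQTHVN	10	nonbinder		Table1
Q92904	DAZL	TQDDYFKDKRVHHFRRS	6	nonbinder		Table1
Q96FV2	SCRN2	VRTLPRFQTQVDRR	10	nonbinder		Table1
Q96FV2	SCRN2	TLPRFQTQVDRR	8	nonbinder		Table1
Q7Z589	EMSY	KITFTKPSTQTTNT	10	nonbinder		Table1
Q13952	NFYC	CLKETLQITQTEVQ	10	nonbinder		Table1
Q9HC84	MUC5B-1	TTLPVLTSTATKST	6	nonbinder		Table1
P53350	PLK1	AASLIQKMLQTDPTAR	10	nonbinder		Table1
Q92499	DDX1	HSGNAQVTQTKF	9	nonbinder		Table1
Q8NBH2	KY	ITSYNSQGTQLTVE	10	nonbinder		Table1
Q06190	PPP2R3A	LQETLTTSSQANLS	10	nonbinder		Table1
Q13618	CUL3	KHSGRQLTLQHHMG	10	nonbinder		Table1
Q9H4B6	SAV1	NQSFLRTPIQRTPH	10	nonbinder		Table1
Q2TV78	MSTL1	EGYRGTANTTTAAYLA	6	nonbinder		Table1
Q6ZU65	UBN2	PLQATISKSQTNPV	10	nonbinder		Table1
Q96SC8	DMRTA2	SSRSAFSPLQPNAS	10	nonbinder		Table1
Q6ZRI0	OTOG	TLQQPLELTASQLPAG	12	nonbinder		Table1
Q96JG9	ZNF469	RAAALPEETRSSRR	6	nonbinder		Table1
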