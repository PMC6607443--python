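# Transcription of the printed PSSM-predicted peptide table.
protein_id	gene	peptide	q_index	label	kd_um	source
Q6LCS3	E4_HPV	LQGRQEDKQTQTPPP	11	binder		Table2
Q8IX07	ZFPM1	PAPPSYSDKGVQTPSK	12	binder		Table2
P11193	VP4_RVA	VTNSLNDISTQTSTI	11	binder	4.2	Table2
P13500	CCL2	DSMDHLDKQTQTPKT	11	binder		Table2
P18583	SON	SRKSRCVSVQTDPT	10	binder		Table2
Q9Y2H9	MAST1	GCTRHQSVQTEDG	9	binder		Table2
P80098	CCL7	QDFMKHLDKKTQTPKL	12	binder		Table2
Q5K4E3	PRSS36	GPDGEETETQTCPP	10	nonbinder		Table2
P20702	ITGAX	GQIAPENGTQTPSP	10	nonbinder		Table2
P03586	MT_TMV	AQPKQKLDTSIQTEYP	12	nonbinder		Table2
Q8IYH5	ZZZ3	KSVAENGDTDTQTSMF	12	nonbinder		Table2
Q5DMI6	DNLJ2_T5	KIEIPTQCPSCGSK	7	nonbinder		Table2
Q92904	DAZL	PQKKSVDRSIQTVVS	11	nonbinder		Table2
Q9NZ56	FMN2	HHRILEAKSIQTSPT	11	nonbinder		Table2
Q13418	ILK	MDDIFTQCREGN	7	nonbinder		Table2
O43432	EIF4G3	DFTPAFADFGRQTPGG	12	nonbinder		Table2
Q99613	EIF3C	ELMASLDQPTQTVVM	11	nonbinder		Table2
O15444	CCL25	NKVFAKLHHNTQTFQA	12	nonbinder		Table2
P20042	EIF2S2	KPFMLDEEGDTQTEET	12	nonbinder		Table2
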