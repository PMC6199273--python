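# Conserved motifs of the ERF/DREB subfamilies (MEME best-matched consensus)
family	motif	consensus	sites	e_value	annotation
ERF	1	WLGTFDTAEEAARAYDRAAFRMRGS	56	3.0e-1007	AP2 domain related
ERF	2	KEKRYRGVRRRPWGKYAAEIRDPSRKGRR	56	5.8e-1049	AP2 domain related
ERF	3	KAKLNFPLEVV	51	5.90E-148	
ERF	4	QEREVVEFEYLDDKLLEELLD	14	1.50E-88	
ERF	5	SLREMKYGCEEGCSPVIALKRKHSMRRK	5	8.20E-32	
ERF	6	LPFNENDSEDMVLYGVLSDAVNSGW	6	1.20E-21	
ERF	7	RIVRIIVTDPDATDSSSDDDE	6	1.70E-20	
ERF	8	DLALLESIRQHLLGDD	8	1.30E-17	
ERF	9	MKYERKFSASLYAFNGIQECM	4	6.70E-13	
ERF	10	QHHHHRQ	7	4.20E-12	
ERF	11	MCGGAIISDFIPGPRGRRLTSDDLW	3	1.30E-10	
ERF	12	RRPLPLDLNLPPPLE	7	8.50E-10	EAR
ERF	13	DGDICPFCNINGCLGCNFF	3	5.30E-07	putative zinc-finger
ERF	14	QQQQQQQQQQ	5	1.70E-05	
ERF	15	SGEPEPVRVTPKRRSPEPS	6	3.00E-05	
ERF	16	RRRVKRYVNEINIE	7	1.10E-04	
ERF	17	YGNTSSSPASSSSLPGGVGEG	5	1.30E-04	
ERF	18	GPIKYTEHRTVTNKL	4	2.10E-03	
ERF	19	NTRTNFWPCSPSPNSRPALPSKIANLLLQRLKARNN	2	8.10E-03	
DREB	1	GKWVSEIREPNKKTRIWLGTFPTAEMAARAYDVA	38	6.1e-919	AP2 domain related
DREB	2	ALALRGSSARLNFPELVNSLPRPASSSPS	38	6.40E-271	CIPK12
DREB	3	PVYRGVRQRKW	37	2.70E-235	AP2 domain related
DREB	4	DIQAAAAKAAAAFR	23	1.40E-54	CIPK12
DREB	5	DEESPLDMPKLLMDMAEGLLLSPPHMVSN	9	7.40E-50	
DREB	6	RKPPAKGSKKGCMKGKGGPEN	7	1.60E-48	CMIV-1
DREB	7	RNGSKSVAETLARWKEYNDHLDSSNDEGK	4	6.70E-16	
DREB	8	PKKRAGRKKFKETRH	4	5.20E-14	CMIII-3
DREB	9	QQHHQYHHHHHHHQH	5	2.60E-12	
DREB	10	QFFKPLEDDHIEQMIZELJDYGYIELC	2	1.20E-07	
DREB	11	WDDLEETADVSLWSY	8	3.90E-06	LWSY
DREB	12	MDARYTDHLDFDFLPPEVGESSSDSGSARRLNLSDEEVLL	2	3.70E-04	
DREB	13	IGLNNLTPSQILZIQAQIQLQ	2	2.70E-03	CMI-3
DREB	14	STSTSTSSSSSS	22	5.10E-03	
DREB	15	LDAKLQAISQ	6	3.60E-02	CMI-2
DREB	16	NVAPVTVRLSPSQIQ	3	4.00E-03	
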