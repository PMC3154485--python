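drug	carrier	condition	k_S	k_off	delta_G_1e-21J	time_unit	variant	source_table
CF	TSL	1 mol% PEG	0.494	0.014	-0.97	minute	full	T1
CF	TSL	3 mol% PEG	1.568	0.026	0.83	minute	full	T1
CF	TSL	4 mol% PEG	1.273	0.039	2.18	minute	full	T1
CF	TSL	10 mol% PEG	2.785	0.089	4.77	minute	full	T1
Verapamil	liposome	Vera-FBS	2.268	0.092	4.71	hour	full	T1
Verapamil	liposome	Vera-HBS	1.912	0.096	3.88	hour	full	T1
Doxorubicin	liposome	Dox-FBS	1.670	0.0037	-10.4	hour	full	T1
Doxorubicin	liposome	Dox-HBS	1.706	0.0056	-12.6	hour	full	T1
Verapamil	liposome	Vera-in vivo	4.561	0.08	11.5	hour	full	T1
Verapamil	liposome	Vera-MLV	3.360	0.04	10.2	hour	full	T1
Doxorubicin	liposome	Dox-in vivo	0.212	0.008	-1.22	hour	full	T1
Doxorubicin	liposome	Dox-MLV	1.387	0.005	-2.32	hour	full	T1
Amiodarone	LNC	pH 2.0	0.028			hour	single_exponential	T1
Amiodarone	LNC	pH 3.0	0.032	0.011	4.52	hour	full	T1
Amiodarone	LNC	pH 4.0	0.033	0.006	3.49	hour	full	T1
Amiodarone	LNC	pH 5.5	0.033	0.004	-0.86	hour	full	T1
Amiodarone	LNC	pH 7.4	0.265	0.003	-9.35	hour	full	T1
BSA	PLLA NC	Mw 16,000	0.719	0.025	0.41	hour	full	T1
BSA	PLLA NC	Mw 51,000	0.754	0.02	-3.3	hour	full	T1
Indomethacin	PECL NC	PLL-coated	0.0182	0.202	11.8	minute	full	T1
Indomethacin	PECL NC	uncoated	0.0156	0.203	11.8	minute	full	T1
Telmisartan	MSNP	pore 12.9 nm	0.192			minute	single_exponential	T2
Telmisartan	MSNP	pore 7.8 nm	0.1			minute	single_exponential	T2
Telmisartan	MSNP	pore 3.6 nm	0.0652			minute	single_exponential	T2
Am80	PEG-PBLA micelle	no additive	3.913	0.013	5.11	day	full	T2
Am80	PEG-PBLA micelle	TPA	7.314	0.067	6.84	day	full	T2
Am80	PEG-PBLA micelle	DMDA	1.272	0.059	6.61	day	full	T2
Am80	PEG-PBLA micelle	DMOA	0.541	0.001	-1.18	day	full	T2
DS	PLNP	0.15 M NaCl	0.381	0.023	3.36	hour	full	T2
DS	PLNP	15 mM NaCl	0.248	0.001	4.90	hour	full	T2
DS	PLNP	0.5 mM NaCl	0.258	0.012	0.64	hour	full	T2
DS	PLNP	DDI water	0.237	0.005	-5.1	hour	full	T2
Estradiol	PLGA NP	PLA/PGA 50:50	0.197	0.019	-1.69	day	full	T2
Estradiol	PLGA NP	PLA/PGA 65:35	0.163	0.004	-2.40	day	full	T2
Estradiol	PLGA NP	PLA/PGA 85:15	0.179	0.007	-3.94	day	full	T2
Savoxepine	PLA NP	303 nm	1.437	0.064	-0.61	day	full	T2
Savoxepine	PLA NP	671 nm	1.792	0.028	-5.52	day	full	T2
Steroid BP	PLGA NP	PLGA 8,000	0.333	0.336	-1.06	day	full	T2
Steroid BP	PLGA NP	PLGA 13,000	0.375	0.04	-1.56	day	full	T2
Steroid BP	PLA NP	PLA 9,000	0.319	0.004	-3.2	day	full	T2
Steroid BP	PLA NP	PLA 14,000	0.099	0.128	-6.73	day	full	T2
Steroid BDP	PLA NP	Control PLA 14,000	5.576	0.344	-0.67	day	full	T2
Doxorubicin	PLLA fibers	dox hydrochloride	0.027	0.001	7.4	minute	full	T3
Doxorubicin	PLLA fibers	dox base	0.041	0.0004	-6.65	minute	full	T3
Avidin	CS-AG fibers	100:0 AG/HP	11.1	0.095	1.03	day	full	T3
Avidin	CS-AG fibers	80:20 AG/HP	11.2	0.064	-2.37	day	full	T3
Avidin	CS-AG fibers	90:10 AG/HP	5.12	0.053	-2.09	day	full	T3
Avidin	CS-AG fibers	50:50 AG/HP	9.89	0.045	-2.64	day	full	T3
PDGF	CS-AG fibers	100:0 AG/HP	0.677	0.027	-4.14	day	full	T3
PDGF	CS-AG fibers	90:10 AG/HP	0.486	0.001	-13.5	day	full	T3
VEGF	PEtU-PDMS/fibrin fibers	10 mg/mL fibrin	0.435	0.009	0.187	day	full	T3
VEGF	PEtU-PDMS/fibrin fibers	20 mg/mL fibrin	0.434	0.017	-1.27	day	full	T3
bFGF	PEtU-PDMS/fibrin fibers	10 mg/mL fibrin	0.289	0.001	0.65	day	full	T3
bFGF	PEtU-PDMS/fibrin fibers	20 mg/mL fibrin	0.242	0.017	-1.94	day	full	T3
GS	MBGHF	2-2.5 mm	0.444	0.005	7.24	hour	full	T3
GS	MBGHF	5-10 mm	0.136	0.012	5.13	hour	full	T3
BSA	hydrogel nanofibers	37C	4.81	0.027	-4.9	day	full	T3
BSA	hydrogel nanofibers	25C	1.585	0.017	-5.47	day	full	T3
BSA	PCL fibers	37C	1.114	0.011	-4.72	day	full	T3
BSA	PCL fibers	25C	1.521	0.011	-6.33	day	full	T3
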