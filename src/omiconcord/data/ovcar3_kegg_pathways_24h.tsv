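pathway_id	pathway_name	functional_system	n_phosphoproteins
hsa04010	MAPK signaling pathway	FS1	22
hsa04012	ErbB signaling pathway	FS1	20
hsa04014	Ras signaling pathway	FS1	21
hsa04015	Rap1 signaling pathway	FS1	17
hsa04020	Calcium signaling pathway	FS1	6
hsa04022	cGMP-PKG signaling pathway	FS1	8
hsa04024	cAMP signaling pathway	FS1	11
hsa04064	NF-kappa B signaling pathway	FS1	7
hsa04066	HIF-1 signaling pathway	FS1	14
hsa04068	FoxO signaling pathway	FS1	14
hsa04071	Sphingolipid signaling pathway	FS1	10
hsa04150	mTOR signaling pathway	FS1	9
hsa04151	PI3K-Akt signaling pathway	FS1	25
hsa04152	AMPK signaling pathway	FS1	7
hsa04310	Wnt signaling pathway	FS1	7
hsa04350	TGF-beta signaling pathway	FS1	4
hsa04370	VEGF signaling pathway	FS1	10
hsa04630	Jak-STAT signaling pathway	FS1	6
hsa04668	TNF signaling pathway	FS1	11
hsa04910	Insulin signaling pathway	FS1	13
hsa04912	GnRH signaling pathway	FS1	11
hsa04913	Ovarian steroidogenesis	FS1	3
hsa04914	Progesterone-mediated oocyte maturation	FS1	10
hsa04915	Estrogen signaling pathway	FS1	9
hsa04916	Melanogenesis	FS1	6
hsa04917	Prolactin signaling pathway	FS1	11
hsa04919	Thyroid hormone signaling pathway	FS1	12
hsa04920	Adipocytokine signaling pathway	FS1	5
hsa04921	Oxytocin signaling pathway	FS1	8
hsa04922	Glucagon signaling pathway	FS1	5
hsa04923	Regulation of lipolysis in adipocytes	FS1	4
hsa04110	Cell cycle	FS1	5
hsa04114	Oocyte meiosis	FS1	6
hsa04510	Focal adhesion	FS1	18
hsa04520	Adherens junction	FS1	9
hsa04540	Gap junction	FS1	6
hsa04550	Signaling pathways regulating pluripotency of stem cells	FS1	12
hsa04810	Regulation of actin cytoskeleton	FS1	12
hsa04261	Adrenergic signaling in cardiomyocytes	FS1	7
hsa04270	Vascular smooth muscle contraction	FS1	7
hsa04320	Dorso-ventral axis formation	FS1	3
hsa04360	Axon guidance	FS1	7
hsa04380	Osteoclast differentiation	FS1	15
hsa04960	Aldosterone-regulated sodium reabsorption	FS1	3
hsa04930	Type II diabetes mellitus	FS2	5
hsa04931	Insulin resistance	FS2	9
hsa04932	Non-alcoholic fatty liver disease (NAFLD)	FS2	8
hsa04720	Long-term potentiation	FS2	6
hsa04722	Neurotrophin signaling pathway	FS2	20
hsa04723	Retrograde endocannabinoid signaling	FS2	5
hsa04725	Cholinergic synapse	FS2	6
hsa04726	Serotonergic synapse	FS2	5
hsa04728	Dopaminergic synapse	FS2	7
hsa04730	Long-term depression	FS2	5
hsa04750	Inflammatory mediator regulation of TRP channels	FS2	7
hsa05014	Amyotrophic lateral sclerosis (ALS)	FS2	3
hsa05020	Prion diseases	FS2	5
hsa05030	Cocaine addiction	FS2	4
hsa05100	Bacterial invasion of epithelial cells	FS2	6
hsa05120	Epithelial cell signaling in Helicobacter pylori infection	FS2	11
hsa05130	Pathogenic Escherichia coli infection	FS2	4
hsa05131	Shigellosis	FS2	7
hsa05132	Salmonella infection	FS2	7
hsa05133	Pertussis	FS2	6
hsa05140	Leishmaniasis	FS2	8
hsa05142	Chagas disease (American trypanosomiasis)	FS2	8
hsa05145	Toxoplasmosis	FS2	9
hsa05152	Tuberculosis	FS2	11
hsa05160	Hepatitis C	FS2	12
hsa05161	Hepatitis B	FS2	15
hsa05162	Measles	FS2	10
hsa05164	Influenza A	FS2	15
hsa05166	HTLV-I infection	FS2	15
hsa05168	Herpes simplex infection	FS2	9
hsa05169	Epstein-Barr virus infection	FS2	14
hsa05200	Pathways in cancer	FS2	28
hsa05202	Transcriptional misregulation in cancer	FS2	10
hsa05203	Viral carcinogenesis	FS2	10
hsa05205	Proteoglycans in cancer	FS2	27
hsa05206	MicroRNAs in cancer	FS2	14
hsa05210	Colorectal cancer	FS2	9
hsa05211	Renal cell carcinoma	FS2	10
hsa05212	Pancreatic cancer	FS2	11
hsa05213	Endometrial cancer	FS2	9
hsa05214	Glioma	FS2	12
hsa05215	Prostate cancer	FS2	13
hsa05216	Thyroid cancer	FS2	7
hsa05218	Melanoma	FS2	11
hsa05219	Bladder cancer	FS2	9
hsa05220	Chronic myeloid leukemia	FS2	11
hsa05221	Acute myeloid leukemia	FS2	12
hsa05222	Small cell lung cancer	FS2	6
hsa05223	Non-small cell lung cancer	FS2	11
hsa05230	Central carbon metabolism in cancer	FS2	11
hsa05231	Choline metabolism in cancer	FS2	12
hsa04062	Chemokine signaling pathway	FS2	13
hsa04611	Platelet activation	FS2	9
hsa04620	Toll-like receptor signaling pathway	FS2	11
hsa04621	NOD-like receptor signaling pathway	FS2	6
hsa04622	RIG-I-like receptor signaling pathway	FS2	4
hsa04650	Natural killer cell mediated cytotoxicity	FS2	11
hsa04660	T cell receptor signaling pathway	FS2	14
hsa04662	B cell receptor signaling pathway	FS2	8
hsa04664	Fc epsilon RI signaling pathway	FS2	12
hsa04666	Fc gamma R-mediated phagocytosis	FS2	10
hsa04670	Leukocyte transendothelial migration	FS2	7
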