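dataset_id	n_reads	IGHV1-2_inferred	IGHV1-2_read	IGHV1-3_inferred	IGHV1-3_read	IGHV4-4_inferred	IGHV4-4_read	IGHV7-4-1_inferred	IGHV7-4-1_read
ERR2567187	225406	*04†	*04, *05	*01	*01	*02	*01, *02	*02	*01, *02
ERR2567189	224871	*02¶	*02, *04	*01	*01, *02	*02, *07	*02, *07		*01
ERR2567192	212646	*02, *04	*02, *04	*01	*01	*02	*02	*01	*01
ERR2567199	240716	*02, *04	*02, *04	*01	*01, *02	*02, *07	*02, *07	*01	*01
ERR2567200	180844	*02, *04	*02, *04	*01	*01, *02	*02, *07	*02, *07	*01	*01
ERR2567201	215909	*02§	*02, *07		*02	*07	*07		
ERR2567204	265106	*04, *06	*04, *06	*01	*01	*02	*02	*02	*01, *02
ERR2567206	262069	*06	*05, *06	*01	*01	*02	*01, *02	*02	*02
ERR2567213	211280	*02	*02		*02	*07	*07		
ERR2567214	276041	*04	*04	*01	*01	*02	*02	*01	*01
ERR2567215	220448	*02, *04	*02, *04	*01	*01, *02	*02, *07	*02, *07	*01	*01
ERR2567217	182276	*02	*02		*02	*07	*07		
ERR2567220	151436	*02¶	*02, *04	*01	*01, *02	*02, *07	*02, *07	*01	*01
ERR2567221	164821	*02¶	*02, *04	*01	*01	*02, *07	*02, *07		
ERR2567223	156379	*02, *06	*02, *06	*01	*01, *02	*02, *07	*02, *07	*02	*02
ERR2567226	117706	*02	*02		*02	*02, *07	*02, *07		*01
ERR2567230	183580	*02	*02	*02	*02	*02, *07	*02, *07		*01
ERR2567231	240347	*02†	*02, *05	*01	*01, *02	*07	*01, *07	*02	*02
ERR2567232	192854	*02, *06	*02, *06	*01	*01, *02	*02, *07	*02, *07	*02	*02
ERR2567240	149185	*02	*02		*02	*07	*07		
ERR2567242	348123	*02¶	*02, *04	*01	*01, *02	*02, *07	*02, *07		*01
ERR2567243	253195	*04†	*04, *05	*01	*01	*02	*01, *02	*02	*01, *02
ERR2567246	223410	*04	*04	*01	*01	*02	*02	*01	*01
ERR2567249	223137	*04†	*04, *05	*01	*01	*02	*01, *02	*02	*01, *02
ERR2567254	241355	*04	*04	*01	*01	*02	*02	*01	*01
ERR2567259	189273	*02†	*02, *05	*01	*01, *02	*07	*01, *07	*02	*02
ERR2567261	308875	*04	*04	*01	*01	*02	*02	*01	*01
ERR2567263	312067	*02	*02	*02	*02	*07	*07		
ERR2567264	226845	*02, *04	*02, *04	*01	*01, *02	*02	*02	*01	*01
ERR2567265	194775	*02, *04	*02, *04	*01	*01, *02	*02, *07	*02, *07	*01	*01
ERR2567266	321732	*04	*04	*01	*01	*02, *07	*02, *07		*01
ERR2567271	168997	*06¶	*04, *06	*01	*01	*02	*02	*02	*01, *02
ERR2567274	184738	*04	*04	*01	*01	*02	*02		*01
ERR2567276	148621	*02, *06	*02, *06	*01	*01, *02	*02, *07	*02, *07	*02	*02
ERR2567277	193732	*02	*02, *04	*01	*01, *02	*02, *07	*02, *07	*01	*01
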