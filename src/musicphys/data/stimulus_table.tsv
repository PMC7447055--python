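album_name	track	start	end	index_ref	valence	energy	tension	grouping
Batman	4	02:31	02:48L	79	7.25	8.12	5.03	ENERGY POS MOD
Batman	9	00:56	01:23	63	4.76	3.96	6.04	VALENCE NEG MOD
Big Fish	8	00:11	00:42	110	6.75	3.90	2.82	TENSION NEG HIGH
Big Fish	15	00:18	00:49	65	4.07	5.04	6.93	VALENCE NEG MOD
Big Fish	15	00:54	01:26	82	5.24	3.70	4.79	ENERGY NEG MOD
Blanc	12	00:39	01:09	52	6.82	4.97	3.46	VALENCE POS HIGH
Blanc	10	00:12	00:42	88	5.03	2.96	4.10	ENERGY NEG HIGH
Cape Fear	2	01:13	01:44	100	3.22	5.09	7.43	TENSION POS MOD
Dances with Wolves	10	00:18	00:46	55	7.04	7.27	4.66	VALENCE POS HIGH
Dracula	5	00:11	00:44	99	4.16	5.22	6.84	TENSION POS MOD
Gladiator	17	00:00	00:29	53	7.07	6.76	4.55	VALENCE POS HIGH
Hellraiser	5	00:00	00:30	69	2.36	7.09	8.24	VALENCE NEG HIGH
Juha	2	01:55	02:26	101	7.57	4.60	2.46	TENSION NEG MOD
Juha	10	00:07	00:40	51	7.30	5.00	3.18	VALENCE POS HIGH
Juha	16	00:00	00:31	81	5.60	3.07	4.01	ENERGY NEG MOD
Juha	18	02:28	03:00	61	5.78	5.97	5.99	VALENCE NEG MOD
Lethal weapon 3	7	00:00	00:29	67	4.72	4.72	6.67	VALENCE NEG HIGH
Man of Galilee CD1	2	00:09	00:42	56	6.67	6.75	5.16	VALENCE POS MOD
Man of Galilee CD1	2	03:02	03:18L	72	7.45	8.39	5.61	ENERGY POS HIGH
Oliver Twist	7	00:53	01:20	80	5.88	6.78	6.10	ENERGY POS MOD
Pride & Prejudice	4	00:02	00:33	105	5.84	5.90	5.67	VALENCE POS MOD
Road To Perdition	6	00:18	00:49	68	8.01	8.27	4.16	TENSION NEG MOD
Running Scared	15	01:44	02:16	86	2.51	6.03	8.01	VALENCE NEG HIGH
Shakespeare In Love	11	00:20	00:51	62	6.57	7.55	5.51	VALENCE POS MOD
Shakespeare In Love	21	00:00	00:29	57	4.28	3.88	5.84	ENERGY NEG HIGH
The Alien Trilogy	11	02:05	02:35	91	3.48	5.58	7.37	VALENCE NEG MOD
The English Patient	8	01:28	01:59	66	3.69	7.09	7.66	TENSION POS HIGH
The Fifth Element	13	00:16	00:48	92	2.58	6.85	8.16	VALENCE NEG HIGH
The Godfather Part III	5	01:11	01:41	107	2.99	6.99	8.12	TENSION POS HIGH
The Untouchables	6	01:38	02:08	71	7.09	4.21	2.75	TENSION NEG HIGH
Vertigo OST	6	02:02	02:33	58	7.45	7.64	4.27	ENERGY POS HIGH
Outbreak	6	00:15	00:45	60	6.03	3.82	4.31	VALENCE POS MOD
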