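site_id	sample_date	region	temperature_c	ph	sulfide_um
TLS	1986-09-09	NZ	44.5	5.8	280-1850
Lip5	2002-01-22	PHL	36.1	5.1-6.0	40
BS1-00	2000-06-21	YNP	41.6	6.4	NA
BS1-01	2001-08-06	YNP	51.6	6.8	1.8
BS2	2000-06-21	YNP	46-51.7	4.6-6.4	NA
BS3.1	2000-06-21	YNP	35.6	6.4	NA
BS3.2T	2000-06-29	YNP	44.4	6.7	NA
BS3.2M	2000-06-29	YNP	44.4	6.7	NA
MV1	2000-06-29	YNP	49-54	5.9	NA
MV2	2000-06-29	YNP	36-44	5.7	NA
MV3	2001-08-07	YNP	34.3	5.8	2.7
MV4	2001-08-07	YNP	50.1	5.7	5.3
MV5	2001-08-07	YNP	39-40	5.7-5.9	4.7
MV6	2002-07-31	YNP	37-40	5.4-5.7	1.3
AT	2001-08-11	YNP	67.4	6.9	27.7
NG2	2000-06-14	YNP	52.5	6.2	NA
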