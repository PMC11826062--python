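site_id	location	fluid_type	ph	temperature_c	si_molal	dic_molal	h2_molal	ch4_molal	formate_molal	acetate_molal
140115Z	Al Banah - Surface	type2	11.3	32.2	1.4E-06	3.4E-05	2.3E-04		3.0E-06	3.2E-06
140115X	Al Banah - Surface	type2	11.4	29.5	2.2E-06	3.1E-05	2.3E-04		4.3E-06	4.1E-06
140115Y	Al Banah - Surface	type2	11.6	24.5	2.2E-06	1.1E-04	2.1E-05		1.7E-06	2.9E-06
140114S	Falej North - Surface	mixed	7.7	21	2.0E-04	4.4E-03	1.5E-08			8.5E-07
140114U	Falej North - Surface	type2	11.4	21.7	7.4E-06	1.8E-04	1.7E-08		3.3E-06	2.5E-06
140114V	Falej North - Surface	type2	11.4	24.4	2.8E-06	2.3E-04	1.7E-07		9.8E-07
140114T	Falej North - Surface	type2	11.4	27.2	1.8E-06	4.2E-05	2.8E-05		5.5E-06	3.0E-06
140114R	Falej North - Surface	type2	11.6	21.1	2.4E-06	4.2E-05	1.2E-08
140113O	Falej South - Surface	type2	11.4	28.4	3.7E-06	5.7E-05	3.9E-05		4.8E-06	3.9E-06
140113P	Falej South - Surface	type2	11.5	25.9	1.9E-06	4.6E-05	6.6E-05		1.6E-06	2.2E-06
140111G	Qafifah - Surface	mixed	8.9	22.6	2.8E-04	4.1E-03	2.4E-07			1.2E-06
140111H	Qafifah - Surface	mixed	10.2	20.2	1.5E-04	1.8E-03	1.1E-06		2.0E-06	6.6E-07
140111I	Qafifah - Surface	mixed	10.9	18.8	1.0E-04	8.5E-04	2.1E-06		1.3E-06	9.2E-07
140111F	Qafifah - Surface	type2	11.6	23.8	1.1E-05	4.1E-05	2.6E-04		1.9E-06	1.8E-06
140116B	Shmait - Surface	mixed	7.9	26.5	3.0E-04	5.1E-03	6.2E-08			1.5E-06
140116C	Shmait - Surface	mixed	8.7	27.3	2.8E-04	4.7E-03	2.2E-06			1.6E-06
140116D	Shmait - Surface	mixed	9.1	27.1	2.6E-04	4.0E-03	1.3E-05			1.4E-06
140117J	Shmait - Surface	mixed	11.3	31.6	4.9E-05	7.0E-05	2.2E-04		5.3E-07
140117I	Shmait - Surface	type2	11.3	32.3	2.0E-06	4.7E-05	2.3E-04		4.9E-07
140117G	Shmait - Surface	type2	11.4	30.5	1.5E-06	1.9E-05	2.8E-06		1.5E-06
140117F	Shmait - Surface	type2	11.5	26.2	2.7E-06	2.9E-05	2.7E-04		1.2E-06	1.5E-06
140117H	Shmait - Surface	type2	11.5	29.6	1.7E-06	2.9E-05	2.3E-04		1.1E-06
140110B	Wadi Dima - Surface	mixed	8.4	23.5	1.8E-04	3.6E-03	7.0E-09		4.4E-07
140112L	Wadi Dima - Surface	mixed	9.8	21.3	1.1E-04	1.9E-03	9.0E-09		7.4E-07
140110D	Wadi Dima - Surface	mixed	10.4	21.8	9.1E-05	8.1E-04	5.6E-08		7.5E-07
140112M	Wadi Dima - Surface	type2	11.4	28.2	5.6E-06	5.2E-05	3.1E-05		7.4E-07
140112K	Wadi Dima - Surface	type2	11.4	26.9	3.9E-06	3.6E-05	4.9E-07		9.4E-07	7.9E-07
140110C	Wadi Dima - Surface	type2	11.4	27	4.3E-06	5.3E-05	6.4E-06		4.2E-06	1.3E-06
NSHQ142014	Well	type2	11.4	34.9	7.0E-06		6.7E-04
NSHQ142015	Well	type2	11.3	35.3	5.0E-06	1.9E-04	2.9E-03		1.7E-06	1.2E-06
NSHQ142016	Well	type2	11.2	35.8	5.0E-06		2.2E-04
NSHQ212015	Well	mixed	7.4	33.7	7.8E-04	2.6E-03			1.1E-06	4.9E-07
NSHQ3B2015	Well	mixed	8.4	30.1	2.5E-04	2.5E-03			1.2E-06	4.7E-07
NSHQ42014	Well	mixed	10.6	35.1	2.0E-04	2.2E-04			1.5E-06	4.4E-06
NSHQ42015	Well	mixed	10.5	33.3	1.5E-05	1.8E-04			2.3E-06	1.4E-06
WAB1032015	Well	mixed	8.2	30.4	4.8E-04	2.3E-03			1.1E-06	4.3E-07
WAB1032016	Well	type1	8.2	33.8	8.5E-04
WAB1042016	Well	mixed	8.5	33.4	2.1E-04
WAB1052016	Well	mixed	8.3	31.6	4.3E-05
WAB1882015	Well	mixed	8.7	34.2	2.3E-04	2.3E-03			1.0E-06	3.8E-06
WAB1882016	Well	mixed	7.6	33	7.9E-04
WAB552015	Well	type2	9.3	30	6.0E-06	2.6E-03			1.4E-06	2.0E-06
WAB552016	Well	type2	9.2	34.7	6.0E-06
WAB562015	Well	type2	10.6	33.3	1.0E-05		1.8E-04
WAB712015	Well	mixed	11.0	33.1	1.7E-05				1.5E-06	6.3E-07
WAB712016	Well	mixed	11.1	34.5	2.4E-05
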