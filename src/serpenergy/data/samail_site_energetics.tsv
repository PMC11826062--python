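site_id	fluid_type	subsurface	ph	si_molal	affinity_hydrogenotrophic	affinity_formatotrophic	affinity_acetoclastic	supply_hydrogenotrophic	supply_formatotrophic	supply_acetoclastic
140115Z	type2	0	11.33	1.38E-06	65.2	97.2	48.1	2.2E+00	7.4E-02	1.5E-01
140115X	type2	0	11.398	2.22E-06	70.4	102.1	49.9	2.2E+00	1.1E-01	2.1E-01
140115Y	type2	0	11.579	2.16E-06	53.5	87.1	47.7	2.8E-01	3.7E-02	1.4E-01
140114S	mixed	0	7.65	2.0E-04	40.3		37.2	1.5E-04		3.2E-02
140114U	type2	0	11.355	7.43E-06	-4.2	97.9	54.0	0.0E+00	8.0E-02	1.3E-01
140114V	type2	0	11.407	2.75E-06	11.0	76.6		4.7E-04	1.9E-02
140114T	type2	0	11.421	1.84E-06	47.6	98.2	43.7	3.3E-01	1.3E-01	1.3E-01
140114R	type2	0	11.585	2.44E-06	-23.8			0.0E+00
140113O	type2	0	11.43	3.68E-06	56.1	100.4	49.5	5.5E-01	1.2E-01	1.9E-01
140113P	type2	0	11.49	1.94E-06	58.6	89.0	45.6	9.6E-01	3.6E-02	1.0E-01
140111G	mixed	0	8.936	2.76E-04	47.9		27.5	2.9E-03		3.3E-02
140111H	mixed	0	10.24	1.45E-04	50.1	49.4	25.5	1.4E-02	2.4E-02	1.7E-02
140111I	mixed	0	10.87	1.0E-04	48.4	55.9	31.0	2.5E-02	1.8E-02	2.9E-02
140111F	type2	0	11.624	1.05E-05	68.0	85.2	38.7	2.8E+00	4.1E-02	6.8E-02
140116B	mixed	0	7.909	3.03E-04	50.1		39.2	7.8E-04		5.8E-02
140116C	mixed	0	8.714	2.79E-04	70.0		29.5	3.8E-02		4.7E-02
140116D	mixed	0	9.104	2.6E-04	89.2		34.4	2.8E-01		4.7E-02
140117J	mixed	0	11.309	4.89E-05	75.4	65.6		4.1E+00	8.7E-03
140117I	type2	0	11.313	1.96E-06	70.4	73.5		3.3E+00	9.0E-03
140117G	type2	0	11.389	1.50E-06	24.8	93.5		1.7E-02	3.4E-02
140117F	type2	0	11.48	2.65E-06	72.4	89.0	45.5	2.1E+00	2.7E-02	6.6E-02
140117H	type2	0	11.485	1.66E-06	69.1	87.6		2.0E+00	2.3E-02
140110B	mixed	0	8.425	1.83E-04	30.0	51.0		5.2E-05	5.5E-03
140112L	mixed	0	9.774	1.11E-04	9.6	43.0		2.2E-05	7.9E-03
140110D	mixed	0	10.394	9.14E-05	15.1	46.7		2.1E-04	8.8E-03
140112M	type2	0	11.376	5.60E-06	44.7	71.3		3.4E-01	1.3E-02
140112K	type2	0	11.379	3.88E-06	2.9	76.4	35.6	3.6E-04	1.8E-02	2.8E-02
140110C	type2	0	11.392	4.26E-06	30.1	89.3	36.7	4.8E-02	9.4E-02	4.7E-02
NSHQ142014	type2	1	11.4	7.00E-06
NSHQ142015	type2	1	11.3	5.00E-06	92.8	70.8	35.6	1.8E+01	3.0E-02	4.3E-02
NSHQ142016	type2	1	11.2	5.00E-06
NSHQ212015	mixed	1	7.4	7.82E-04
NSHQ3B2015	mixed	1	8.4	2.47E-04
NSHQ42014	mixed	1	10.6	1.98E-04		60.5	38.5		2.3E-02	1.7E-01
NSHQ42015	mixed	1	10.5	1.50E-05		59.4	24.2		3.4E-02	3.4E-02
WAB1032015	mixed	1	8.2	4.8E-04
WAB1032016	type1	1	8.2	8.48E-04
WAB1042016	mixed	1	8.5	2.1E-04
WAB1052016	mixed	1	8.3	4.30E-05
WAB1882015	mixed	1	8.7	2.32E-04		34.0	24.5		8.5E-03	9.3E-02
WAB1882016	mixed	1	7.6	7.85E-04
WAB552015	type2	1	9.3	6.00E-06
WAB552016	type2	1	9.2	6.00E-06
WAB562015	type2	1	10.6	1.00E-05
WAB712015	mixed	1	11	1.70E-05
WAB712016	mixed	1	11.1	2.40E-05
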