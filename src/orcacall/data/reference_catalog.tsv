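group_id	call_class	n_calls	min_f_lo	min_f_hi	max_f_lo	max_f_hi	start_f_lo	start_f_hi	end_f_lo	end_f_hi	delta_f_lo	delta_f_hi	duration_lo	duration_hi	n_extrema_lo	n_extrema_hi	n_inflections_lo	n_inflections_hi	fm_rate_lo	fm_rate_hi	sideband_lo	sideband_hi
BC01	whistle	18	2.2	11.8	3.9	14.6	2.2	12.8	2.9	14.5	1.1	6.2	0.2	3.7	9	21	8	20	3.4	50.2
BC02	whistle	35	1.0	5.4	1.8	8.4	1.1	6.3	1.0	8.4	0.4	4.4	0.1	1.5	0	9	0	8	0	38
BC03	whistle	5	6.8	8.2	10.0	11.5	7.6	8.4	7.5	9.7	3.2	3.8	3.9	11.3	15	72	14	71	3.3	6.3
BC04	whistle	61	3.9	15.0	9.1	29.3	3.9	27	5.7	29.1	0.3	20.3	0.05	1.4	0	7	0	6	0	14.3
BC05	burst_pulse	5	0.6	1.2	1.1	5.6	0.6	1.5	0.7	3.4	0.3	4.5	0.5	1.2	0	5	0	4	0	6.5	0.3	0.7
BC06	burst_pulse	6	4.6	8.1	5.2	10.7	4.8	10.1	4.6	8.3	0.6	2.8	0.2	0.6	4	8	5	7	9.3	28.2	0.2	0.8
BC07	burst_pulse	4	2.7	4.7	4.1	6.3	3.6	6.3	2.9	6.3	1.4	1.6	0.1	0.3	1	6	0	5	0	18.1	0.4	0.7
BC08	pulsed_middle	2	3.6	4.2	5.1	5.2	5.4	8.7	3.9	8.0	1	1.6	0.1	0.5	1	1	0	0	0	0	0.8	0.9
BC09	transition	6	0.9	4.1	1.5	5.5	1.1	4.4	1.2	5.5	0.5	3.4	0.1	1.2	1	10	0	9	0	13.9	0.4	0.9
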