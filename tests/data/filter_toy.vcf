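##fileformat=VCFv4.2
##source=chelonia
##contig=<ID=s,length=2000>
##INFO=<ID=FS,Number=1,Type=Float,Description="FS">
##INFO=<ID=QD,Number=1,Type=Float,Description="QD">
##INFO=<ID=MQ,Number=1,Type=Float,Description="MQ">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQRankSum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="ReadPosRankSum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	ind1
s	100	.	A	G	100	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	150	.	A	G	59.9	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	200	.	A	G	100	PASS	FS=60.1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	250	.	A	G	100	PASS	FS=60;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	300	.	A	G	100	PASS	FS=1;QD=1.9;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	350	.	A	G	100	PASS	FS=1;QD=2;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	400	.	A	G	100	PASS	FS=1;QD=20;MQ=39;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	450	.	A	G	100	PASS	FS=1;QD=20;MQ=40;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	500	.	A	G	100	PASS	FS=1;QD=20;MQ=60;MQRankSum=-20.5;ReadPosRankSum=0	GT:DP	0|1:20
s	550	.	A	G	100	PASS	FS=1;QD=20;MQ=60;MQRankSum=-19;ReadPosRankSum=0	GT:DP	0|1:20
s	600	.	A	G	100	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=-8.5	GT:DP	0|1:20
s	650	.	A	G	100	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=-8	GT:DP	0|1:20
s	700	.	A	G,T	100	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	750	.	A	AT	70	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	753	.	A	G	100	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	756	.	A	G	100	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	800	.	A	AT	50	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	803	.	A	G	100	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	900	.	A	G	100	PASS	.	GT:DP	0|1:20
s	950	.	A	G	60	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	1000	.	A	G	10	PASS	FS=1;QD=1;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	1100	.	AT	GC	100	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	1200	.	A	G	100	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	1205	.	C	CTT	61	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	1210	.	A	G	100	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	1211	.	A	G	100	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	1300	.	A	G	100	PASS	FS=59.9;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	1400	.	A	G	100	PASS	FS=1;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
s	1500	.	A	G	100	PASS	FS=1;QD=20;MQ=60;MQRankSum=-30;ReadPosRankSum=-9	GT:DP	0|1:20
s	1600	.	A	G	100	PASS	FS=1;QD=20;MQ=60;MQRankSum=0;ReadPosRankSum=0	GT:DP	0|1:20
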