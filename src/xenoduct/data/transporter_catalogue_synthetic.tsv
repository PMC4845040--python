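gene_symbol	family	clinically_relevant	transport_class
SLC16A1	SLC	1	influx
SLC15A1	SLC	1	influx
SLC22A1	SLC	1	influx
SLC22A7	SLC	1	influx
SLC10A1	SLC	1	influx
SLC22A9	SLC	1	influx
SLC10A2	SLC	1	influx
SLC15A2	SLC	1	influx
SLC22A12	SLC	1	influx
SLC22A8	SLC	1	influx
SLC22A6	SLC	1	influx
SLC22A2	SLC	1	influx
SLC47A1	SLC	1	efflux
SLC47A2	SLC	1	efflux
SLC29A1	SLC	1	influx/efflux
SLC29A2	SLC	1	influx/efflux
SLC51A	OST	1	influx/efflux
SLC51B	OST	1	influx/efflux
SLC22A5	SLC	1	influx/efflux
SLC22A11	SLC	0	influx/efflux
SLC22A4	SLC	0	influx/efflux
SLC2A1	SLC	0	none
SLC5A9	SLC	0	none
SLC22A15	SLC	0	none
SLC30A10	SLC	0	none
SLC25A22	SLC	0	none
SLC43A1	SLC	0	none
SLC3A2	SLC	0	none
SLC41A2	SLC	0	none
SLC5A11	SLC	0	none
SLC7A5	SLC	0	none
SLC25A11	SLC	0	none
SLC25A10	SLC	0	none
SLC16A3	SLC	0	none
SLC25A42	SLC	0	none
SLC1A4	SLC	0	none
SLC20A1	SLC	0	none
SLC23A2	SLC	0	none
SLC2A10	SLC	0	none
SLC5A3	SLC	0	none
SLC25A1	SLC	0	none
SLC39A8	SLC	0	none
SLC10A7	SLC	0	none
SLC25A4	SLC	0	none
SLC26A2	SLC	0	none
SLC39A7	SLC	0	none
SLC17A5	SLC	0	none
SLC22A3	SLC	0	none
SLC37A3	SLC	0	none
SLC20A2	SLC	0	none
SLC25A5	SLC	0	none
SLC5A12	SLC	0	none
SLC1A1	SLC	0	none
SLC1A2	SLC	0	none
SLC1A3	SLC	0	none
SLC1A5	SLC	0	none
SLC1A6	SLC	0	none
SLC1A7	SLC	0	none
SLC1A8	SLC	0	none
SLC1A9	SLC	0	none
SLC1A10	SLC	0	none
SLC1A11	SLC	0	none
SLC1A12	SLC	0	none
SLC1A13	SLC	0	none
SLC1A14	SLC	0	none
SLC2A2	SLC	0	none
SLC2A3	SLC	0	none
SLC2A4	SLC	0	none
SLC2A5	SLC	0	none
SLC2A6	SLC	0	none
SLC2A7	SLC	0	none
SLC2A8	SLC	0	none
SLC2A9	SLC	0	none
SLC2A11	SLC	0	none
SLC2A12	SLC	0	none
SLC2A13	SLC	0	none
SLC2A14	SLC	0	none
SLC3A1	SLC	0	none
SLC3A3	SLC	0	none
SLC3A4	SLC	0	none
SLC3A5	SLC	0	none
SLC3A6	SLC	0	none
SLC3A7	SLC	0	none
SLC3A8	SLC	0	none
SLC3A9	SLC	0	none
SLC3A10	SLC	0	none
SLC3A11	SLC	0	none
SLC3A12	SLC	0	none
SLC3A13	SLC	0	none
SLC3A14	SLC	0	none
SLC4A1	SLC	0	none
SLC4A2	SLC	0	none
SLC4A3	SLC	0	none
SLC4A4	SLC	0	none
SLC4A5	SLC	0	none
SLC4A6	SLC	0	none
SLC4A7	SLC	0	none
SLC4A8	SLC	0	none
SLC4A9	SLC	0	none
SLC4A10	SLC	0	none
SLC4A11	SLC	0	none
SLC4A12	SLC	0	none
SLC4A13	SLC	0	none
SLC4A14	SLC	0	none
SLC5A1	SLC	0	none
SLC5A2	SLC	0	none
SLC5A4	SLC	0	none
SLC5A5	SLC	0	none
SLC5A6	SLC	0	none
SLC5A7	SLC	0	none
SLC5A8	SLC	0	none
SLC5A10	SLC	0	none
SLC5A13	SLC	0	none
SLC5A14	SLC	0	none
SLC6A1	SLC	0	none
SLC6A2	SLC	0	none
SLC6A3	SLC	0	none
SLC6A4	SLC	0	none
SLC6A5	SLC	0	none
SLC6A6	SLC	0	none
SLC6A7	SLC	0	none
SLC6A8	SLC	0	none
SLC6A9	SLC	0	none
SLC6A10	SLC	0	none
SLC6A11	SLC	0	none
SLC6A12	SLC	0	none
SLC6A13	SLC	0	none
SLC6A14	SLC	0	none
SLC7A1	SLC	0	none
SLC7A2	SLC	0	none
SLC7A3	SLC	0	none
SLC7A4	SLC	0	none
SLC7A6	SLC	0	none
SLC7A7	SLC	0	none
SLC7A8	SLC	0	none
SLC7A9	SLC	0	none
SLC7A10	SLC	0	none
SLC7A11	SLC	0	none
SLC7A12	SLC	0	none
SLC7A13	SLC	0	none
SLC7A14	SLC	0	none
SLC8A1	SLC	0	none
SLC8A2	SLC	0	none
SLC8A3	SLC	0	none
SLC8A4	SLC	0	none
SLC8A5	SLC	0	none
SLC8A6	SLC	0	none
SLC8A7	SLC	0	none
SLC8A8	SLC	0	none
SLC8A9	SLC	0	none
SLC8A10	SLC	0	none
SLC8A11	SLC	0	none
SLC8A12	SLC	0	none
SLC8A13	SLC	0	none
SLC8A14	SLC	0	none
SLC9A1	SLC	0	none
SLC9A2	SLC	0	none
SLC9A3	SLC	0	none
SLC9A4	SLC	0	none
SLC9A5	SLC	0	none
SLC9A6	SLC	0	none
SLC9A7	SLC	0	none
SLC9A8	SLC	0	none
SLC9A9	SLC	0	none
SLC9A10	SLC	0	none
SLC9A11	SLC	0	none
SLC9A12	SLC	0	none
SLC9A13	SLC	0	none
SLC9A14	SLC	0	none
SLC10A3	SLC	0	none
SLC10A4	SLC	0	none
SLC10A5	SLC	0	none
SLC10A6	SLC	0	none
SLC10A8	SLC	0	none
SLC10A9	SLC	0	none
SLC10A10	SLC	0	none
SLC10A11	SLC	0	none
SLC10A12	SLC	0	none
SLC10A13	SLC	0	none
SLC10A14	SLC	0	none
SLC11A1	SLC	0	none
SLC11A2	SLC	0	none
SLC11A3	SLC	0	none
SLC11A4	SLC	0	none
SLC11A5	SLC	0	none
SLC11A6	SLC	0	none
SLC11A7	SLC	0	none
SLC11A8	SLC	0	none
SLC11A9	SLC	0	none
SLC11A10	SLC	0	none
SLC11A11	SLC	0	none
SLC11A12	SLC	0	none
SLC11A13	SLC	0	none
SLC11A14	SLC	0	none
SLC12A1	SLC	0	none
SLC12A2	SLC	0	none
SLC12A3	SLC	0	none
SLC12A4	SLC	0	none
SLC12A5	SLC	0	none
SLC12A6	SLC	0	none
SLC12A7	SLC	0	none
SLC12A8	SLC	0	none
SLC12A9	SLC	0	none
SLC12A10	SLC	0	none
SLC12A11	SLC	0	none
SLC12A12	SLC	0	none
SLC12A13	SLC	0	none
SLC12A14	SLC	0	none
SLC13A1	SLC	0	none
SLC13A2	SLC	0	none
SLC13A3	SLC	0	none
SLC13A4	SLC	0	none
SLC13A5	SLC	0	none
SLC13A6	SLC	0	none
SLC13A7	SLC	0	none
SLC13A8	SLC	0	none
SLC13A9	SLC	0	none
SLC13A10	SLC	0	none
SLCO4C1	SLCO	1	influx
SLCO2B1	SLCO	1	influx
SLCO1B3	SLCO	1	influx
SLCO1B1	SLCO	1	influx
SLCO1A2	SLCO	1	influx
SLCO3A1	SLCO	0	none
SLCO1B7	SLCO	0	none
SLCO1C1	SLCO	0	none
SLCO2A1	SLCO	0	none
SLCO4A1	SLCO	0	none
SLCO5A1	SLCO	0	none
ABCB1	ABC	1	efflux
ABCG2	ABC	1	efflux
ABCC2	ABC	1	efflux
ABCC3	ABC	1	efflux
ABCC4	ABC	1	efflux
ABCC6	ABC	1	efflux
ABCB11	ABC	1	efflux
ABCC5	ABC	1	efflux
ABCD3	ABC	0	none
ABCA3	ABC	0	none
ABCA9	ABC	0	none
ABCC10	ABC	0	none
ABCB4	ABC	0	none
ABCA2	ABC	0	none
ABCA8	ABC	0	none
ABCA1	ABC	0	none
ABCA4	ABC	0	none
ABCA5	ABC	0	none
ABCA6	ABC	0	none
ABCA7	ABC	0	none
ABCA10	ABC	0	none
ABCA11	ABC	0	none
ABCA12	ABC	0	none
ABCA13	ABC	0	none
ABCB5	ABC	0	none
ABCB6	ABC	0	none
ABCB7	ABC	0	none
ABCB8	ABC	0	none
ABCB9	ABC	0	none
ABCB10	ABC	0	none
ABCC1	ABC	0	none
ABCC7	ABC	0	none
ABCC8	ABC	0	none
ABCC9	ABC	0	none
ABCC11	ABC	0	none
ABCC12	ABC	0	none
ABCD1	ABC	0	none
ABCD2	ABC	0	none
ATP1B1	ATP	0	none
ATP2B1	ATP	0	none
ATP11A	ATP	0	none
ATP5H	ATP	0	none
ATP9B	ATP	0	none
ATP5G3	ATP	0	none
ATP1B2	ATP	0	none
ATP1B3	ATP	0	none
ATP1B4	ATP	0	none
ATP2B2	ATP	0	none
ATP2B3	ATP	0	none
ATP2B4	ATP	0	none
ATP3B1	ATP	0	none
ATP3B2	ATP	0	none
ATP3B3	ATP	0	none
ATP3B4	ATP	0	none
ATP4B1	ATP	0	none
ATP4B2	ATP	0	none
ATP4B3	ATP	0	none
ATP4B4	ATP	0	none
ATP5B1	ATP	0	none
ATP5B2	ATP	0	none
ATP5B3	ATP	0	none
ATP5B4	ATP	0	none
ATP6B1	ATP	0	none
ATP6B2	ATP	0	none
ANXA9	ANXA	0	none
ANXA11	ANXA	0	none
ANXA6	ANXA	0	none
ANXA1	ANXA	0	none
ANXA2	ANXA	0	none
ANXA3	ANXA	0	none
ANXA4	ANXA	0	none
ANXA5	ANXA	0	none
ANXA7	ANXA	0	none
ANXA8	ANXA	0	none
ANXA10	ANXA	0	none
AQP1	AQP	0	none
AQP2	AQP	0	none
AQP3	AQP	0	none
AQP4	AQP	0	none
AQP5	AQP	0	none
AQP6	AQP	0	none
AQP7	AQP	0	none
AQP8	AQP	0	none
AQP9	AQP	0	none
AQP10	AQP	0	none
AQP11	AQP	0	none
AQP12	AQP	0	none
AQP13	AQP	0	none
CACNA2D4	CACNA	0	none
CACNA1A	CACNA	0	none
CACNA1B	CACNA	0	none
CACNA1C	CACNA	0	none
CACNA1D	CACNA	0	none
CACNA1E	CACNA	0	none
CACNA1F	CACNA	0	none
CACNA1G	CACNA	0	none
CACNA1H	CACNA	0	none
CACNA1I	CACNA	0	none
CLCN1	CLCN	0	none
CLCN2	CLCN	0	none
CLCN3	CLCN	0	none
CLCN4	CLCN	0	none
CLCN5	CLCN	0	none
CLCN6	CLCN	0	none
CLCN7	CLCN	0	none
CLCNKA	CLCN	0	none
CLCNKB	CLCN	0	none
CLCC1	CLCN	0	none
KCNJ2	KCNJ	0	none
KCNJ1	KCNJ	0	none
KCNJ3	KCNJ	0	none
KCNJ4	KCNJ	0	none
KCNJ5	KCNJ	0	none
KCNJ6	KCNJ	0	none
KCNJ7	KCNJ	0	none
KCNJ8	KCNJ	0	none
KCNJ9	KCNJ	0	none
KCNJ10	KCNJ	0	none
KCNJ11	KCNJ	0	none
KCNJ12	KCNJ	0	none
KCNJ13	KCNJ	0	none
KCNJ14	KCNJ	0	none
KCNJ15	KCNJ	0	none
KCNJ16	KCNJ	0	none
KCNQ1	KCNQ	0	none
KCNQ2	KCNQ	0	none
KCNQ3	KCNQ	0	none
KCNQ4	KCNQ	0	none
KCNQ5	KCNQ	0	none
MFSD11	MFSD	0	none
MFSD1	MFSD	0	none
MFSD2	MFSD	0	none
MFSD3	MFSD	0	none
MFSD4	MFSD	0	none
MFSD5	MFSD	0	none
MFSD6	MFSD	0	none
MFSD7	MFSD	0	none
MFSD8	MFSD	0	none
MFSD9	MFSD	0	none
MFSD10	MFSD	0	none
MFSD12	MFSD	0	none
MFSD13	MFSD	0	none
MFSD14	MFSD	0	none
PEX16	PEX	0	none
PEX26	PEX	0	none
PEX1	PEX	0	none
PEX2	PEX	0	none
PEX3	PEX	0	none
PEX5	PEX	0	none
PEX6	PEX	0	none
PEX7	PEX	0	none
RHAG	RHAG	0	none
RHBG	RHAG	0	none
RHCG	RHAG	0	none
SCARB1	SCARB	0	none
SCARB2	SCARB	0	none
SCARB3	SCARB	0	none
SCN8A	SCN	0	none
SCN1A	SCN	0	none
SCN2A	SCN	0	none
SCN3A	SCN	0	none
SCN4A	SCN	0	none
SCN5A	SCN	0	none
SCN6A	SCN	0	none
SCN7A	SCN	0	none
SCN9A	SCN	0	none
SCN10A	SCN	0	none
SFXN1	SFXN	0	none
SFXN2	SFXN	0	none
SFXN3	SFXN	0	none
SFXN4	SFXN	0	none
SFXN5	SFXN	0	none
TRPV1	TRPV	0	none
TRPV2	TRPV	0	none
TRPV3	TRPV	0	none
TRPV4	TRPV	0	none
TRPV5	TRPV	0	none
TRPV6	TRPV	0	none
VDAC1	VDAC	0	none
VDAC2	VDAC	0	none
VDAC3	VDAC	0	none
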