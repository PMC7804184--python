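surface,anchor,category,value,duration_days
in 2012,2020-01-01,ABSOLUTE_DATE,2012,
since Nov 2015,2020-01-01,ABSOLUTE_DATE,2015-11,
in March 2007,2018-05-04,ABSOLUTE_DATE,2007-03,
September 1999,2020-01-01,ABSOLUTE_DATE,1999-09,
Sept 2004,2020-01-01,ABSOLUTE_DATE,2004-09,
12 March 2015,2020-01-01,ABSOLUTE_DATE,2015-03-12,
3rd of June 2014,2020-01-01,ABSOLUTE_DATE,2014-06-03,
1 January 2000,2020-01-01,ABSOLUTE_DATE,2000-01-01,
21/07/2013,2020-01-01,ABSOLUTE_DATE,2013-07-21,
05.11.1998,2020-01-01,ABSOLUTE_DATE,1998-11-05,
2016-09-30,2020-01-01,ABSOLUTE_DATE,2016-09-30,
around 1995,2020-01-01,ABSOLUTE_DATE,1995,
31/04/2015,2020-01-01,ABSOLUTE_DATE,2015,
three years ago,2020-08-15,RELATIVE_DATE,2017-08,
one year ago,2020-08-15,RELATIVE_DATE,2019-08,
two months ago,2020-08-15,RELATIVE_DATE,2020-06,
six months ago,2020-08-15,RELATIVE_DATE,2020-02,
18 months ago,2020-08-15,RELATIVE_DATE,2019-02,
2 weeks ago,2020-08-15,RELATIVE_DATE,2020-08-01,
a week ago,2020-08-15,RELATIVE_DATE,2020-08-08,
10 days ago,2020-08-15,RELATIVE_DATE,2020-08-05,
four years ago,2012-06-01,RELATIVE_DATE,2008-06,
twelve months ago,2012-06-01,RELATIVE_DATE,2011-06,
three weeks ago,2012-06-01,RELATIVE_DATE,2012-05-11,
five days ago,2012-06-01,RELATIVE_DATE,2012-05-27,
2 years ago,2019-03-10,RELATIVE_DATE,2017-03,
a month ago,2019-03-10,RELATIVE_DATE,2019-02,
3 year history of hallucinosis,2019-03-10,RELATIVE_DATE,2016-03,
at the age of 16,2020-01-01,AGE,AGE16Y,
at the age of eight,2020-01-01,AGE,AGE8Y,
the age of 8,2020-01-01,AGE,AGE8Y,
aged 19,2020-01-01,AGE,AGE19Y,
when she was 21,2020-01-01,AGE,AGE21Y,
when he was seventeen,2020-01-01,AGE,AGE17Y,
since he was 19 years old,2020-01-01,AGE,AGE19Y,
at age 30,2020-01-01,AGE,AGE30Y,
for the past six months,2020-01-01,DURATION,,180
for the past 2 years,2020-01-01,DURATION,,730
over the last three weeks,2020-01-01,DURATION,,21
during the last four months,2020-01-01,DURATION,,120
for 3 years,2020-01-01,DURATION,,1095
for ten days,2020-01-01,DURATION,,10
a long time ago,2020-01-01,NONE,,
recently,2020-01-01,NONE,,
for many years,2020-01-01,NONE,,
aged 150,2020-01-01,NONE,,
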