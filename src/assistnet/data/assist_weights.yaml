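# WHO-ASSIST v3.0 item response weights.
#
# Q2 asks about frequency of use in the past 3 months; Q3-Q5 ask about the
# frequency of harm experiences (urge to use, health/social/legal/financial
# problems, failure to meet normal expectations); Q6-Q7 ask whether a close
# other expressed concern / whether the respondent tried and failed to cut
# down, with "yes" split by recency.  The per-substance involvement score is
# the sum of these weights.  Q5 is not administered for tobacco.
#
# The loader expands this table to substance x item x level; per-substance
# deviations can be supplied under `overrides`.
levels:
  frequency: [never, once_or_twice, monthly, weekly, daily_or_almost_daily]
  recency: [never, yes_not_past_3_months, yes_past_3_months]
weights:
  q2: {never: 0, once_or_twice: 2, monthly: 3, weekly: 4, daily_or_almost_daily: 6}
  q3: {never: 0, once_or_twice: 3, monthly: 4, weekly: 5, daily_or_almost_daily: 6}
  q4: {never: 0, once_or_twice: 4, monthly: 5, weekly: 6, daily_or_almost_daily: 7}
  q5: {never: 0, once_or_twice: 5, monthly: 6, weekly: 7, daily_or_almost_daily: 8}
  q6: {never: 0, yes_not_past_3_months: 3, yes_past_3_months: 6}
  q7: {never: 0, yes_not_past_3_months: 3, yes_past_3_months: 6}
excluded_items:
  tobacco: [q5]
overrides: {}
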